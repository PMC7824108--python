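"""Sixplex TMT and native SRM method generation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmtlipid import chem, tmt_method
from tmtlipid.chem import parse_lipid_shorthand, registry_lookup
from tmtlipid.tmt_method import (
    H_PER_LABEL,
    LPA_PA_PANEL,
    TMT_TAG_NOMINAL,
    NotLabelableError,
    build_native_transitions,
    build_sixplex_transitions,
    count_label_sites,
    default_channels,
    fa_panel,
    read_transition_list,
    tmt_precursor,
    validate_transitions,
    write_transition_list,
)


class TestLabelSites:
    def test_fatty_acid_takes_one_tag(self):
        k = count_label_sites(parse_lipid_shorthand("FA(20:4)"))
        assert k.k_labels == 1
        assert k.site_types == ("carboxy",)

    def test_phosphate_monoester_takes_one_tag(self):
        k = count_label_sites(parse_lipid_shorthand("LPA(18:1)"))
        assert k.site_types == ("phospho_monoester",)

    def test_two_carboxy_species_take_two_tags(self):
        assert count_label_sites(registry_lookup("20-carboxy-LTB4")).k_labels == 2
        assert count_label_sites(registry_lookup("tetranor-PGDM")).k_labels == 2

    @pytest.mark.parametrize("name", ["LPC(16:0)", "LPE(18:1)", "DAG(18:1/18:1)"])
    def test_phosphodiester_and_neutral_lipids_not_labelable(self, name):
        with pytest.raises(NotLabelableError):
            count_label_sites(parse_lipid_shorthand(name))


class TestTmtPrecursor:
    @pytest.mark.parametrize(
        "name,mz,charge",
        [
            ("FA(20:4)", 606.48, 1),
            ("LPA(18:1)", 738.50, 1),
            ("LPA(16:0)", 712.49, 1),
        ],
    )
    def test_singly_labeled_precursors(self, name, mz, charge):
        sp = parse_lipid_shorthand(name)
        assert tmt_precursor(sp) == (pytest.approx(mz, abs=0.005), charge)

    def test_doubly_labeled_divalent_ion(self):
        sp = registry_lookup("20-carboxy-LTB4")
        mz, charge = tmt_precursor(sp)
        assert charge == 2
        assert mz == pytest.approx(485.34, abs=0.005)

    def test_divalent_matches_hand_arithmetic_for_all_two_carboxy_species(self):
        """(M - 2H + 2 tag)/2, written out independently of the implementation."""
        for name in ("20-carboxy-LTB4", "tetranor-PGDM"):
            sp = registry_lookup(name)
            m = sp.monoisotopic_mass()
            expected = (m - 2 * 1.00783 + 2 * 303.25) / 2
            mz, charge = tmt_precursor(sp)
            assert charge == 2
            assert mz == pytest.approx(expected, abs=0.005)

    def test_exact_tag_mode_substitutes_tag_mass(self):
        sp = parse_lipid_shorthand("FA(20:4)")
        mz_nominal, _ = tmt_precursor(sp)
        mz_exact, _ = tmt_precursor(sp, rule_mode="exact_tag", tag_mass=304.0)
        assert mz_exact == pytest.approx(mz_nominal + 0.75, abs=0.005)

    @given(
        c=st.integers(min_value=12, max_value=24), d=st.integers(min_value=0, max_value=4)
    )
    @settings(derandomize=True, max_examples=40)
    def test_precursor_increases_with_carbon_number(self, c, d):
        if d >= c or d >= c + 2:
            return
        lighter, _ = tmt_precursor(parse_lipid_shorthand(f"FA({c}:{d})"))
        heavier, _ = tmt_precursor(parse_lipid_shorthand(f"FA({c + 2}:{d})"))
        assert heavier > lighter


class TestSixplexBuilder:
    def test_one_species_six_channels(self):
        tl = build_sixplex_transitions([parse_lipid_shorthand("FA(20:4)")])
        assert len(tl) == 6
        assert {t.precursor_mz for t in tl} == {606.48}
        assert [t.product_mz for t in tl] == [126.15, 127.15, 128.15, 129.15, 130.15, 131.15]
        assert all(t.polarity == "positive" for t in tl)
        assert all(t.collision_energy == 46.0 for t in tl)

    def test_unlabelable_species_skipped_with_warning(self):
        tl = build_sixplex_transitions(
            [parse_lipid_shorthand("FA(20:4)"), parse_lipid_shorthand("LPC(16:0)")]
        )
        assert len(tl) == 6
        assert len(tl.warnings) == 1
        assert "LPC(16:0)" in tl.warnings[0]

    def test_lpa_pa_panel_yields_78_transitions(self, lpa_pa_panel):
        """5 LPA + 8 unique PA species (one printed duplicate) x 6 channels."""
        tl = build_sixplex_transitions(lpa_pa_panel)
        assert len(tl) == 78

    def test_isobaric_property(self, lpa_pa_panel):
        """All channels of one species share a precursor; reporters differ."""
        tl = build_sixplex_transitions(lpa_pa_panel)
        by_species = {}
        for t in tl:
            by_species.setdefault(t.species_name, []).append(t)
        for trans in by_species.values():
            assert len({t.precursor_mz for t in trans}) == 1
            assert len({t.product_mz for t in trans}) == 6

    def test_reporter_spacing_strictly_one(self):
        mzs = [ch.reporter_mz for ch in default_channels()]
        assert all(
            b - a == pytest.approx(1.0, abs=1e-9) for a, b in zip(mzs, mzs[1:])
        )

    def test_exactly_one_bridging_channel(self):
        channels = default_channels(bridge_label="131")
        assert [ch.label for ch in channels if ch.role == "bridging"] == ["131"]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            build_sixplex_transitions([])

    def test_duplicate_channel_labels_rejected(self):
        ch = default_channels()
        with pytest.raises(ValueError, match="duplicate"):
            build_sixplex_transitions(
                [parse_lipid_shorthand("FA(20:4)")], channels=[ch[0], ch[0]]
            )

    def test_fa_panel_covers_chain_lengths_12_to_24(self):
        names = fa_panel()
        assert names[0] == "FA(12:0)" and names[-1] == "FA(24:0)"
        assert len(names) == 13


class TestNativeBuilder:
    def test_printed_method_values(self, native_panel):
        tl = build_native_transitions(native_panel)
        got = {
            t.species_name: (t.precursor_mz, t.product_mz, t.polarity) for t in tl
        }
        assert got["LPC(16:0)"] == (496.35, 184.1, "positive")
        assert got["LPE(18:1)"] == (480.3, 339.3, "positive")
        assert got["DAG(18:1/18:1)"] == (636.6, 339.3, "positive")
        assert got["LPA(16:0)"] == (409.4, 153.1, "negative")
        assert got["LPA(18:1)"] == (435.4, 153.1, "negative")
        assert got["PA(36:2)"] == (699.6, 153.1, "negative")

    def test_novel_lpe_gets_computed_transition(self):
        """LPE(18:0): [M+H]+ Q1 and neutral loss of phosphoethanolamine Q3."""
        tl = build_native_transitions([parse_lipid_shorthand("LPE(18:0)")])
        t = tl.transitions[0]
        assert t.precursor_mz == pytest.approx(482.32, abs=0.005)
        assert t.product_mz == pytest.approx(341.31, abs=0.005)

    def test_novel_lpc_gets_phosphocholine_product(self):
        tl = build_native_transitions([parse_lipid_shorthand("LPC(18:1)")])
        t = tl.transitions[0]
        assert t.product_mz == 184.1
        assert t.precursor_mz == pytest.approx(522.36, abs=0.01)

    def test_computed_mode_agrees_with_stored_for_lpe(self):
        tl = build_native_transitions(
            [parse_lipid_shorthand("LPE(18:1)")], prefer_registry=False
        )
        t = tl.transitions[0]
        assert round(t.precursor_mz, 1) == 480.3
        assert round(t.product_mz, 1) == 339.3

    def test_species_without_native_rule_rejected(self):
        with pytest.raises(ValueError, match="native"):
            build_native_transitions([parse_lipid_shorthand("PA(34:1)")])


class TestRoundTripAndValidation:
    def test_csv_round_trip_is_lossless(self, tmp_path, lpa_pa_panel):
        tl = build_sixplex_transitions(lpa_pa_panel)
        path = tmp_path / "transitions.csv"
        write_transition_list(tl, path)
        back = read_transition_list(path)
        assert back.to_frame().equals(tl.to_frame())
        assert len(path.read_text().splitlines()) == 79  # header + 78 rows

    def test_native_round_trip_keeps_polarity_and_empty_channel(self, tmp_path, native_panel):
        tl = build_native_transitions(native_panel)
        path = tmp_path / "native.csv"
        write_transition_list(tl, path)
        back = read_transition_list(path)
        assert all(t.channel is None for t in back)
        assert [t.polarity for t in back] == [t.polarity for t in tl]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species,precursor_mz,polarity,product_mz,channel,collision_energy\n")
        with pytest.raises(ValueError, match="charge"):
            read_transition_list(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "species,precursor_mz,charge,polarity,product_mz,channel,collision_energy\n"
            "FA(20:4),606.48,one,positive,126.15,126,46\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_transition_list(path)

    def test_sixplex_list_self_consistent(self, lpa_pa_panel):
        tl = build_sixplex_transitions(lpa_pa_panel)
        report = validate_transitions(tl, tolerance=0.01)
        assert report.ok
        assert report.n_checked == 78

    def test_native_dag_flagged_lpc_not(self, native_panel):
        """The stored DAG Q1 (636.6) is ~2 m/z off every common adduct of
        C39H72O5; the audit must flag it and leave LPC(16:0) alone."""
        tl = build_native_transitions(native_panel)
        report = validate_transitions(tl, tolerance=0.3)
        flagged = {f["species"] for f in report.flagged}
        assert "DAG(18:1/18:1)" in flagged
        assert "LPC(16:0)" not in flagged

    def test_validation_never_mutates(self, lpa_pa_panel):
        tl = build_sixplex_transitions(lpa_pa_panel)
        before = tl.to_frame().copy()
        validate_transitions(tl, tolerance=1e-9)
        assert tl.to_frame().equals(before)

    def test_oracle_equivalence_over_shipped_panels(self, lpa_pa_panel):
        """Every emitted TMT precursor equals (M - k*1.00783 + k*303.25)/k
        recomputed here by hand from the species formula."""
        panel = lpa_pa_panel + [
            registry_lookup(n)
            for n in ("12-HETE", "20-HETE", "PGE2", "TXB2", "AA",
                      "20-carboxy-LTB4", "tetranor-PGDM")
        ] + [parse_lipid_shorthand(n) for n in fa_panel()]
        tl = build_sixplex_transitions(panel)
        by_name = {sp.display_name: sp for sp in panel}
        for t in tl:
            sp = by_name[t.species_name]
            k = sp.n_carboxy + sp.n_phospho_monoester
            expected = (sp.monoisotopic_mass() - k * H_PER_LABEL + k * TMT_TAG_NOMINAL) / k
            assert math.isclose(t.precursor_mz, round(expected, 2), abs_tol=1e-9)
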
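"""Sixplex aminoxyTMT SRM method generation, plus the native (unlabeled) method.

The labeling chemistry attaches one TMT tag per carboxy group (DMTMM
activation) or phosphate monoester (EDC activation). Derivatized species are
monitored in positive mode as ``[M - k*H + k*303.25]^(k+)`` with the six
isobaric reporter ions 126.15–131.15 as products; a species with two carboxy
groups takes two tags and flies as a divalent precursor. Lipids without a
labelable site (LPC, LPE, DAG) are monitored by a native SRM method whose
printed transitions are stored verbatim, with computed fallbacks for novel
LPC/LPE species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from tmtlipid.chem import (
    ELECTRON_MASS,
    PROTON_MASS,
    LipidSpecies,
    formula_mass,
    parse_formula,
    resolve_species,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TMTChannel",
    "LabelSiteCount",
    "Transition",
    "TransitionList",
    "ValidationReport",
    "NotLabelableError",
    "default_channels",
    "count_label_sites",
    "tmt_precursor",
    "build_sixplex_transitions",
    "build_native_transitions",
    "write_transition_list",
    "read_transition_list",
    "validate_transitions",
    "TMT_TAG_NOMINAL",
    "H_PER_LABEL",
    "DEFAULT_COLLISION_ENERGY",
    "NATIVE_SRM_REGISTRY",
    "PHOSPHOCHOLINE_FRAGMENT_MZ",
    "PHOSPHOETHANOLAMINE_NEUTRAL_LOSS",
    "LPA_PA_PANEL",
    "fa_panel",
]

#: Nominal per-tag precursor mass offset of the aminoxyTMT sixplex reagent, Da,
#: as used by the instrument method ([M - H + 303.25]+ per label).
TMT_TAG_NOMINAL = 303.25
#: Hydrogen replaced per attached tag in the nominal precursor rule, Da.
H_PER_LABEL = 1.00783
#: Collision energy for TMT-derivatized compounds, eV (positive mode).
DEFAULT_COLLISION_ENERGY = 46.0

#: Sixplex reporter product ions at triple-quad unit resolution.
DEFAULT_REPORTER_MZ = {
    "126": 126.15,
    "127": 127.15,
    "128": 128.15,
    "129": 129.15,
    "130": 130.15,
    "131": 131.15,
}

#: Exact sixplex reporter fine masses, selectable for high-resolution work.
EXACT_REPORTER_MZ = {
    "126": 126.127726,
    "127": 127.124761,
    "128": 128.134436,
    "129": 129.131471,
    "130": 130.141145,
    "131": 131.138180,
}

#: Protonated phosphocholine head-group fragment C5H15NO4P+ (LPC product ion).
PHOSPHOCHOLINE_FRAGMENT_MZ = round(
    formula_mass(parse_formula("C5H15NO4P")) - ELECTRON_MASS, 1
)
#: Phosphoethanolamine neutral loss C2H8NO4P (LPE product-ion rule), Da.
PHOSPHOETHANOLAMINE_NEUTRAL_LOSS = formula_mass(parse_formula("C2H8NO4P"))


class NotLabelableError(ValueError):
    """Species has no carboxy group or phosphate monoester to derivatize."""


@dataclass(frozen=True)
class TMTChannel:
    """One reporter channel of the sixplex set."""

    label: str
    reporter_mz: float
    role: str = "sample"  # "sample" or "bridging"


def default_channels(
    bridge_label: str = "131", exact_reporters: bool = False
) -> list[TMTChannel]:
    """The sixplex channel set 126–131 with one channel flagged as bridging."""
    table = EXACT_REPORTER_MZ if exact_reporters else DEFAULT_REPORTER_MZ
    if bridge_label not in table:
        raise ValueError(f"bridge label {bridge_label!r} not in {sorted(table)}")
    return [
        TMTChannel(lbl, mz, "bridging" if lbl == bridge_label else "sample")
        for lbl, mz in table.items()
    ]


@dataclass(frozen=True)
class LabelSiteCount:
    """Number and kind of TMT tags a species takes; sets the precursor charge."""

    k_labels: int
    site_types: tuple[str, ...]


def count_label_sites(species: LipidSpecies) -> LabelSiteCount:
    """Count derivatizable sites; the precursor charge equals the tag count.

    Raises :class:`NotLabelableError` for species with neither a carboxy group
    nor a phosphate monoester (LPC/LPE: the phosphate oxygens are both
    esterified; DAG: no acidic group) — route those to the native method.
    """
    k = species.n_carboxy + species.n_phospho_monoester
    if k < 1:
        raise NotLabelableError(
            f"{species.display_name} has no carboxy group or phosphate "
            "monoester and cannot be TMT-derivatized"
        )
    sites = ("carboxy",) * species.n_carboxy + (
        "phospho_monoester",
    ) * species.n_phospho_monoester
    return LabelSiteCount(k_labels=k, site_types=sites)


def tmt_precursor(
    species: LipidSpecies,
    k: LabelSiteCount | None = None,
    rule_mode: str = "paper_nominal",
    tag_mass: float | None = None,
) -> tuple[float, int]:
    """Precursor m/z and charge of the TMT-derivatized species.

    ``(M_mono - k*1.00783 + k*tag)/k`` with tag = 303.25 in the default
    ``paper_nominal`` mode; ``exact_tag`` mode substitutes a user-supplied
    instrument-calibrated tag mass. A doubly labeled species (two carboxy
    groups) is emitted as its divalent ion. m/z is rounded to 2 decimals.
    """
    if k is None:
        k = count_label_sites(species)
    if k.k_labels < 1:
        raise NotLabelableError(f"{species.display_name}: k_labels must be >= 1")
    if rule_mode == "paper_nominal":
        tag = TMT_TAG_NOMINAL
    elif rule_mode == "exact_tag":
        tag = TMT_TAG_NOMINAL if tag_mass is None else tag_mass
    else:
        raise ValueError(f"rule_mode must be 'paper_nominal' or 'exact_tag': {rule_mode!r}")
    m = species.monoisotopic_mass()
    n = k.k_labels
    mz = (m - n * H_PER_LABEL + n * tag) / n
    return round(mz, 2), n


@dataclass(frozen=True)
class Transition:
    """One SRM channel: Q1 precursor → Q3 product with acquisition settings."""

    species_name: str
    precursor_mz: float
    precursor_charge: int
    polarity: str  # "positive" | "negative"
    product_mz: float
    channel: str | None = None  # reporter label; None for native mode
    collision_energy: float = DEFAULT_COLLISION_ENERGY
    retention_metadata: str | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("precursor_mz and product_mz must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative: {self.polarity!r}")
        if self.channel is not None and self.polarity != "positive":
            raise ValueError("TMT transitions are acquired in positive mode")


@dataclass
class TransitionList:
    """Ordered transitions plus method metadata (column, gradient, config hash)."""

    transitions: list[Transition] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": t.species_name,
                    "precursor_mz": t.precursor_mz,
                    "charge": t.precursor_charge,
                    "polarity": t.polarity,
                    "product_mz": t.product_mz,
                    "channel": t.channel if t.channel is not None else "",
                    "collision_energy": t.collision_energy,
                }
                for t in self.transitions
            ],
            columns=CSV_COLUMNS,
        )


CSV_COLUMNS = [
    "species",
    "precursor_mz",
    "charge",
    "polarity",
    "product_mz",
    "channel",
    "collision_energy",
]


def _dedupe_panel(panel: Sequence[LipidSpecies]) -> list[LipidSpecies]:
    seen: set[tuple] = set()
    out = []
    for sp in panel:
        key = (sp.lipid_class, sp.formula.hill(), sp.display_name.replace(" ", ""))
        if key in seen:
            logger.warning("duplicate panel entry %s dropped", sp.display_name)
            continue
        seen.add(key)
        out.append(sp)
    return out


def build_sixplex_transitions(
    panel: Sequence[LipidSpecies],
    channels: Sequence[TMTChannel] | None = None,
    collision_energy: float = DEFAULT_COLLISION_ENERGY,
    rule_mode: str = "paper_nominal",
    tag_mass: float | None = None,
) -> TransitionList:
    """Build the sixplex TMT SRM method for a panel.

    Each labelable species contributes one transition per channel; because the
    tags are isobaric all channels of a species share one precursor m/z and
    differ only in the reporter product. Species without labelable sites are
    skipped with a warning (they belong in the native method). Duplicate panel
    entries are deduplicated with a warning. Ordering is deterministic:
    panel order, then channel order.
    """
    if not panel:
        raise ValueError("empty panel")
    if channels is None:
        channels = default_channels()
    if not 1 <= len(channels) <= 6:
        raise ValueError(f"expected 1-6 channels, got {len(channels)}")
    labels = [ch.label for ch in channels]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate channel labels: {labels}")

    tl = TransitionList(
        metadata={"mode": "tmt", "rule_mode": rule_mode, "collision_energy": collision_energy}
    )
    n_labelable = 0
    for sp in _dedupe_panel(panel):
        try:
            k = count_label_sites(sp)
        except NotLabelableError as exc:
            msg = f"skipped (not labelable): {exc}"
            logger.warning(msg)
            tl.warnings.append(msg)
            continue
        n_labelable += 1
        mz, charge = tmt_precursor(sp, k, rule_mode=rule_mode, tag_mass=tag_mass)
        for ch in channels:
            tl.transitions.append(
                Transition(
                    species_name=sp.display_name,
                    precursor_mz=mz,
                    precursor_charge=charge,
                    polarity="positive",
                    product_mz=ch.reporter_mz,
                    channel=ch.label,
                    collision_energy=collision_energy,
                )
            )
    if n_labelable == 0:
        raise ValueError("no labelable species in panel")
    return tl


# ---------------------------------------------------------------------------
# Native (non-labeled) SRM method
# ---------------------------------------------------------------------------

#: Printed instrument-method transitions, stored verbatim: these are tuned
#: unit-resolution values and are not re-derived (see validate_transitions for
#: the consistency audit against computed adduct masses).
NATIVE_SRM_REGISTRY: dict[tuple[str, int, int], tuple[float, float, str]] = {
    ("LPC", 16, 0): (496.35, 184.1, "positive"),
    ("LPE", 18, 1): (480.3, 339.3, "positive"),
    ("DAG", 36, 2): (636.6, 339.3, "positive"),
    ("LPA", 16, 0): (409.4, 153.1, "negative"),
    ("LPA", 18, 1): (435.4, 153.1, "negative"),
    ("PA", 36, 2): (699.6, 153.1, "negative"),
}

#: |computed - stored| above this (m/z) attaches a validation note.
NATIVE_DISCREPANCY_TOLERANCE = 0.3


def _native_computed(species: LipidSpecies) -> tuple[float, float, str]:
    """Computed native Q1/Q3 for LPC/LPE: [M+H]+ and the head-group rule.

    LPC fragments to the protonated phosphocholine head group (184.1); LPE
    loses neutral phosphoethanolamine (141.0191 Da) from the protonated
    precursor.
    """
    mh = species.monoisotopic_mass() + PROTON_MASS
    if species.lipid_class == "LPC":
        return round(mh, 2), PHOSPHOCHOLINE_FRAGMENT_MZ, "positive"
    if species.lipid_class == "LPE":
        return round(mh, 2), round(mh - PHOSPHOETHANOLAMINE_NEUTRAL_LOSS, 2), "positive"
    raise ValueError(
        f"no native SRM rule for {species.display_name} "
        f"(class {species.lipid_class}); only registry species and novel "
        "LPC/LPE are supported"
    )


def build_native_transitions(
    panel: Sequence[LipidSpecies],
    collision_energy: float = DEFAULT_COLLISION_ENERGY,
    prefer_registry: bool = True,
) -> TransitionList:
    """Build the native (non-derivatized) SRM method.

    Registry species get their stored instrument transitions verbatim (default);
    novel LPC/LPE species get computed [M+H]+ precursors and head-group product
    rules. With ``prefer_registry=False`` every species that has a computed rule
    uses it. When a registry species' computed and stored Q1 differ by more
    than 0.3 m/z a validation note is attached.
    """
    if not panel:
        raise ValueError("empty panel")
    tl = TransitionList(metadata={"mode": "native"})
    for sp in _dedupe_panel(panel):
        key = (sp.lipid_class, sp.carbons, sp.double_bonds)
        stored = NATIVE_SRM_REGISTRY.get(key)
        if stored is not None and prefer_registry:
            q1, q3, polarity = stored
            if sp.lipid_class in ("LPC", "LPE"):
                cq1, _, _ = _native_computed(sp)
                if abs(cq1 - q1) > NATIVE_DISCREPANCY_TOLERANCE:
                    tl.warnings.append(
                        f"{sp.display_name}: stored Q1 {q1} differs from "
                        f"computed {cq1} by more than {NATIVE_DISCREPANCY_TOLERANCE}"
                    )
        elif sp.lipid_class in ("LPC", "LPE"):
            q1, q3, polarity = _native_computed(sp)
        elif stored is not None:
            q1, q3, polarity = stored
        else:
            raise ValueError(
                f"no native SRM rule for {sp.display_name}; add it to the "
                "native registry or use the TMT method"
            )
        tl.transitions.append(
            Transition(
                species_name=sp.display_name,
                precursor_mz=q1,
                precursor_charge=1,
                polarity=polarity,
                product_mz=q3,
                channel=None,
                collision_energy=collision_energy,
            )
        )
    return tl


# ---------------------------------------------------------------------------
# CSV round trip + validation
# ---------------------------------------------------------------------------


def write_transition_list(tl: TransitionList, destination, sep: str = ",") -> None:
    """Write a transition list as CSV (or TSV with ``sep='\\t'``).

    Columns: species,precursor_mz,charge,polarity,product_mz,channel,
    collision_energy. The round trip through :func:`read_transition_list`
    is lossless.
    """
    if len(tl) == 0:
        raise ValueError("refusing to write an empty transition list")
    tl.to_frame().to_csv(destination, index=False, sep=sep)


def read_transition_list(source, sep: str = ",") -> TransitionList:
    """Read a transition-list CSV written by :func:`write_transition_list`."""
    df = pd.read_csv(source, sep=sep, dtype={"channel": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transition CSV missing columns: {missing}")
    tl = TransitionList(metadata={"source": str(source)})
    for idx, row in df.iterrows():
        try:
            ch = row["channel"]
            ch = None if (pd.isna(ch) or str(ch) == "") else str(ch)
            tl.transitions.append(
                Transition(
                    species_name=str(row["species"]),
                    precursor_mz=float(row["precursor_mz"]),
                    precursor_charge=int(row["charge"]),
                    polarity=str(row["polarity"]),
                    product_mz=float(row["product_mz"]),
                    channel=ch,
                    collision_energy=float(row["collision_energy"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed transition CSV row {idx + 2}: {exc}") from exc
    return tl


#: Adduct rules used to audit native Q1 values: class → (delta m/z, polarity).
_NATIVE_ADDUCTS = {
    "LPC": (PROTON_MASS, "positive"),  # [M+H]+
    "LPE": (PROTON_MASS, "positive"),
    # [M+NH4]+ — neutral DAGs ionize as ammonium adducts in NH4HCO3 mobile phase
    "DAG": (
        formula_mass(parse_formula("NH4")) - ELECTRON_MASS,
        "positive",
    ),
    "LPA": (-PROTON_MASS, "negative"),  # [M-H]-
    "PA": (-PROTON_MASS, "negative"),
}


@dataclass
class ValidationReport:
    """Result of auditing stored precursor m/z against computed values."""

    flagged: list[dict] = field(default_factory=list)
    n_checked: int = 0
    tolerance: float = 0.0

    @property
    def ok(self) -> bool:
        return not self.flagged


def validate_transitions(
    tl: TransitionList,
    tolerance: float = 0.01,
    registry=None,
) -> ValidationReport:
    """Recompute every precursor m/z from its molecular formula and flag
    entries that disagree with the stored value by more than ``tolerance``.

    TMT entries are recomputed with the nominal tag rule; native entries with
    the class adduct rule ([M+H]+ for LPC/LPE, [M+NH4]+ for DAG, [M-H]- for
    LPA/PA). The input list is never mutated.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    report = ValidationReport(tolerance=tolerance)
    for t in tl:
        sp = resolve_species(t.species_name, registry)
        if t.channel is not None:
            computed, _ = tmt_precursor(sp)
        else:
            adduct = _NATIVE_ADDUCTS.get(sp.lipid_class)
            if adduct is None:
                continue  # no audit rule; skip silently
            delta, _pol = adduct
            computed = round(sp.monoisotopic_mass() + delta, 2)
        report.n_checked += 1
        if abs(computed - t.precursor_mz) > tolerance:
            report.flagged.append(
                {
                    "species": t.species_name,
                    "channel": t.channel,
                    "stored_mz": t.precursor_mz,
                    "computed_mz": computed,
                    "delta": round(computed - t.precursor_mz, 4),
                }
            )
    return report


# ---------------------------------------------------------------------------
# Built-in panels
# ---------------------------------------------------------------------------

#: The targeted LPA/PA panel: five LPA species and nine PA entries as printed
#: in the acquisition method (PA 36:2 appears twice there and is deduplicated
#: at build time).
LPA_PA_PANEL: list[str] = [
    "LPA(16:0)",
    "LPA(18:0)",
    "LPA(18:1)",
    "LPA(18:2)",
    "LPA(20:4)",
    "PA(32:0)",
    "PA(34:1)",
    "PA(34:2)",
    "PA(36:0)",
    "PA(36:2)",
    "PA(36:3)",
    "PA(36:2)",
    "PA(36:4)",
    "PA(38:4)",
]


def fa_panel(
    carbons: Iterable[int] = range(12, 25), double_bonds: Iterable[int] = (0,)
) -> list[str]:
    """Free fatty acid panel names covering chain lengths 12–24 by default."""
    return [f"FA({c}:{d})" for c in carbons for d in double_bonds if d < c]
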
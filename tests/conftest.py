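import pytest

from tmtlipid import chem


@pytest.fixture(scope="session")
def stability_species() -> tuple[str, ...]:
    """Small panel mixing a fatty acid, an oxylipin and phosphate lipids."""
    return ("FA(20:4)", "12-HETE", "LPA(18:1)", "PA(36:2)")


@pytest.fixture(scope="session")
def lpa_pa_panel():
    from tmtlipid.tmt_method import LPA_PA_PANEL

    return [chem.resolve_species(name) for name in LPA_PA_PANEL]


@pytest.fixture(scope="session")
def native_panel():
    names = [
        "LPC(16:0)",
        "LPE(18:1)",
        "DAG(18:1/18:1)",
        "LPA(16:0)",
        "LPA(18:1)",
        "PA(36:2)",
    ]
    return [chem.parse_lipid_shorthand(n) for n in names]
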
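"""Molecular-formula arithmetic, lipid shorthand parsing, and the oxylipin registry.

Masses are computed from a small hard-coded element table (IUPAC monoisotopic
values to six decimals, average to three) so that every m/z the package emits
is reproducible from first principles.

Lipid shorthand follows the field's ``CLASS(c:d)`` convention, where *c* is the
total number of acyl carbons and *d* the total number of acyl double bonds.
Per-chain notation such as ``PA(18:1/18:1)`` is accepted and summed to totals;
sn-position and double-bond location are not modeled (SRM on a triple quad
cannot resolve them anyway).
"""

from __future__ import annotations

import csv
import difflib
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ChemicalFormula",
    "LipidSpecies",
    "FormulaError",
    "LipidNameError",
    "RegistryError",
    "MONOISOTOPIC_MASS",
    "AVERAGE_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "parse_formula",
    "formula_mass",
    "combine",
    "parse_lipid_shorthand",
    "registry_lookup",
    "resolve_species",
    "load_registry",
    "DEFAULT_REGISTRY",
    "SHORTHAND_CLASSES",
]

# IUPAC 2021 element masses. Monoisotopic to 6 decimals, average to 3.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Na": 22.989769,
    "K": 38.963706,
}

AVERAGE_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "K": 39.098,
}

#: Mass of a proton (charge carrier in protonation/deprotonation), Da.
PROTON_MASS = 1.007276
#: Electron rest mass, Da (cation m/z = neutral mass - n_e * electron mass).
ELECTRON_MASS = 0.000549


class FormulaError(ValueError):
    """Malformed formula string, unknown element, or infeasible arithmetic."""


class LipidNameError(ValueError):
    """Unparseable or chemically implausible lipid shorthand name."""


class RegistryError(KeyError):
    """Name not found in the species registry."""


@dataclass(frozen=True)
class ChemicalFormula:
    """Immutable element→count map with mass evaluation and arithmetic.

    Zero-count elements are never stored, so equality is well defined
    element-wise. Addition and subtraction are element-wise; subtraction
    that would go negative raises :class:`FormulaError`.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for el, n in self.element_counts.items():
            if not isinstance(n, int):
                raise FormulaError(f"non-integer count for element {el!r}: {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}: {n}")
            if n > 0:
                cleaned[el] = n
        object.__setattr__(self, "element_counts", cleaned)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __iter__(self):
        return iter(self.element_counts)

    def __bool__(self) -> bool:
        return bool(self.element_counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return combine(self, other, "add")

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return combine(self, other, "subtract")

    def mass(self, mode: str = "monoisotopic") -> float:
        return formula_mass(self, mode)

    def hill(self) -> str:
        """Hill-notation string: C first, then H, then other elements alphabetically."""
        parts = []
        order = [el for el in ("C", "H") if el in self.element_counts]
        order += sorted(el for el in self.element_counts if el not in ("C", "H"))
        for el in order:
            n = self.element_counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.hill()


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation formula string like ``"C20H32O2"``.

    Raises :class:`FormulaError` naming the offending token for unknown
    element symbols or malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"empty or non-string formula: {text!r}")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ChemicalFormula(counts)


def formula_mass(f: ChemicalFormula, mode: str = "monoisotopic") -> float:
    """Mass of a formula in Da, as the sum of per-element masses."""
    if mode == "monoisotopic":
        table = MONOISOTOPIC_MASS
    elif mode == "average":
        table = AVERAGE_MASS
    else:
        raise ValueError(f"mode must be 'monoisotopic' or 'average', got {mode!r}")
    total = 0.0
    for el, n in f.element_counts.items():
        if el not in table:
            raise FormulaError(f"element {el!r} missing from {mode} mass table")
        total += n * table[el]
    return total


def combine(a: ChemicalFormula, b: ChemicalFormula, op: str = "add") -> ChemicalFormula:
    """Element-wise sum or difference of two formulas.

    Mass additivity holds exactly: ``mass(a+b) == mass(a) + mass(b)`` up to
    floating-point rounding. Subtraction that would produce a negative count
    raises :class:`FormulaError` (infeasible formula).
    """
    if op == "add":
        counts = dict(a.element_counts)
        for el, n in b.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return ChemicalFormula(counts)
    if op == "subtract":
        counts = dict(a.element_counts)
        for el, n in b.element_counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"infeasible formula: subtracting {b.hill()} from {a.hill()} "
                    f"leaves {el} negative"
                )
            counts[el] = new
        return ChemicalFormula(counts)
    raise ValueError(f"op must be 'add' or 'subtract', got {op!r}")


@dataclass(frozen=True)
class LipidSpecies:
    """A targeted lipid: name, class, composition, formula and labelable sites.

    ``n_carboxy`` and ``n_phospho_monoester`` count the functional groups that
    aminoxyTMT chemistry can derivatize (carboxyls via DMTMM activation,
    phosphate monoesters via EDC). Phosphodiester lipids (LPC, LPE) carry
    neither and cannot be labeled.
    """

    display_name: str
    lipid_class: str
    formula: ChemicalFormula
    carbons: int | None = None
    double_bonds: int | None = None
    n_carboxy: int = 0
    n_phospho_monoester: int = 0

    @property
    def n_label_sites(self) -> int:
        return self.n_carboxy + self.n_phospho_monoester

    def monoisotopic_mass(self) -> float:
        return formula_mass(self.formula, "monoisotopic")


# Composition rules per shorthand class: (formula builder, n_carboxy, n_phospho).
# Builders take total acyl carbons c and total double bonds d.
def _fa(c: int, d: int) -> dict[str, int]:
    return {"C": c, "H": 2 * c - 2 * d, "O": 2}


def _lpa(c: int, d: int) -> dict[str, int]:
    return {"C": c + 3, "H": 2 * c + 7 - 2 * d, "O": 7, "P": 1}


def _pa(c: int, d: int) -> dict[str, int]:
    return {"C": c + 3, "H": 2 * c + 5 - 2 * d, "O": 8, "P": 1}


def _lpc(c: int, d: int) -> dict[str, int]:
    return {"C": c + 8, "H": 2 * c + 18 - 2 * d, "N": 1, "O": 7, "P": 1}


def _lpe(c: int, d: int) -> dict[str, int]:
    return {"C": c + 5, "H": 2 * c + 12 - 2 * d, "N": 1, "O": 7, "P": 1}


def _dag(c: int, d: int) -> dict[str, int]:
    return {"C": c + 3, "H": 2 * c + 4 - 2 * d, "O": 5}


#: class → (builder, n_carboxy, n_phospho_monoester, n_chains)
SHORTHAND_CLASSES: dict[str, tuple] = {
    "FA": (_fa, 1, 0, 1),
    "LPA": (_lpa, 0, 1, 1),
    "PA": (_pa, 0, 1, 2),
    "LPC": (_lpc, 0, 0, 1),
    "LPE": (_lpe, 0, 0, 1),
    "DAG": (_dag, 0, 0, 2),
}

_SHORTHAND = re.compile(
    r"^\s*([A-Za-z]+)\s*\(\s*(\d+)\s*:\s*(\d+)\s*(?:/\s*(\d+)\s*:\s*(\d+)\s*)?\)\s*$"
)


def parse_lipid_shorthand(name: str) -> LipidSpecies:
    """Parse ``CLASS(c:d)`` or ``CLASS(c1:d1/c2:d2)`` shorthand into a species.

    Per-chain notation is summed to total composition; the display name keeps
    the form the caller wrote. Chemically implausible compositions (more
    double bonds than the chain can hold, two chains given for a one-chain
    class) raise :class:`LipidNameError`.
    """
    m = _SHORTHAND.match(name)
    if m is None:
        raise LipidNameError(f"unparseable lipid shorthand: {name!r}")
    cls = m.group(1).upper()
    if cls not in SHORTHAND_CLASSES:
        raise LipidNameError(
            f"unknown lipid class {cls!r} in {name!r}; "
            f"known classes: {', '.join(sorted(SHORTHAND_CLASSES))}"
        )
    builder, n_carboxy, n_phospho, n_chains = SHORTHAND_CLASSES[cls]

    chains = [(int(m.group(2)), int(m.group(3)))]
    if m.group(4) is not None:
        chains.append((int(m.group(4)), int(m.group(5))))
    if len(chains) == 2 and n_chains == 1:
        raise LipidNameError(f"{cls} carries a single acyl chain; got two in {name!r}")

    for c, d in chains:
        if c < 1:
            raise LipidNameError(f"implausible chain length {c} in {name!r}")
        # A c-carbon acyl chain has at most c-1 C=C bonds beyond the carbonyl.
        if d >= c:
            raise LipidNameError(
                f"double bonds exceed chain capacity in {name!r} ({c}:{d})"
            )

    c_tot = sum(c for c, _ in chains)
    d_tot = sum(d for _, d in chains)
    counts = builder(c_tot, d_tot)
    if any(n < 0 for n in counts.values()):
        raise LipidNameError(f"composition {name!r} yields a negative element count")
    return LipidSpecies(
        display_name=name.strip(),
        lipid_class=cls,
        formula=ChemicalFormula(counts),
        carbons=c_tot,
        double_bonds=d_tot,
        n_carboxy=n_carboxy,
        n_phospho_monoester=n_phospho,
    )


# ---------------------------------------------------------------------------
# Oxylipin / eicosanoid registry
# ---------------------------------------------------------------------------

#: name → (formula, n_carboxy, n_phospho_monoester, synonyms)
#: Positional isomers (12-HETE vs 20-HETE) share a formula and are
#: distinguished only by name and retention time, which SRM cannot resolve.
_DEFAULT_REGISTRY_ROWS: list[tuple[str, str, int, int, tuple[str, ...]]] = [
    ("12-HETE", "C20H32O3", 1, 0, ()),
    ("20-HETE", "C20H32O3", 1, 0, ()),
    ("PGE2", "C20H32O5", 1, 0, ("prostaglandin E2",)),
    ("TXB2", "C20H34O6", 1, 0, ("thromboxane B2",)),
    ("AA", "C20H32O2", 1, 0, ("arachidonic acid", "FA(20:4)")),
    ("20-carboxy-LTB4", "C20H30O6", 2, 0, ("20-carboxy leukotriene B4",)),
    # Tetranor metabolite of PGD2: a C16 prostane-dioic acid. Two carboxyls
    # is the invariant the pipeline relies on; the formula is configurable.
    ("tetranor-PGDM", "C16H24O7", 2, 0, ()),
]


def _build_registry(
    rows: Iterable[tuple[str, str, int, int, tuple[str, ...]]],
) -> dict[str, LipidSpecies]:
    reg: dict[str, LipidSpecies] = {}
    for name, formula, n_cooh, n_po4, synonyms in rows:
        sp = LipidSpecies(
            display_name=name,
            lipid_class="OXYLIPIN",
            formula=parse_formula(formula),
            n_carboxy=n_cooh,
            n_phospho_monoester=n_po4,
        )
        reg[name.lower()] = sp
        for syn in synonyms:
            reg[syn.lower()] = sp
    return reg


DEFAULT_REGISTRY: dict[str, LipidSpecies] = _build_registry(_DEFAULT_REGISTRY_ROWS)


def registry_lookup(
    name: str, registry: Mapping[str, LipidSpecies] | None = None
) -> LipidSpecies:
    """Look up an oxylipin/eicosanoid by name (case-insensitive, synonym-aware).

    Raises :class:`RegistryError` listing the nearest registered names when
    the lookup fails.
    """
    reg = DEFAULT_REGISTRY if registry is None else registry
    key = name.strip().lower()
    if key in reg:
        return reg[key]
    near = difflib.get_close_matches(key, list(reg), n=3, cutoff=0.4)
    suggestion = f"; nearest: {', '.join(near)}" if near else ""
    raise RegistryError(f"species {name!r} not found in registry{suggestion}")


def load_registry(path) -> dict[str, LipidSpecies]:
    """Load an extension registry from CSV.

    Columns: ``name, formula, n_carboxy, n_phospho_monoester, synonyms``
    (synonyms ``;``-separated, may be empty). Entries override the built-in
    defaults when merged by the caller.
    """
    rows: list[tuple[str, str, int, int, tuple[str, ...]]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "formula", "n_carboxy", "n_phospho_monoester"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"registry CSV must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for rec in reader:
            synonyms = tuple(
                s.strip() for s in (rec.get("synonyms") or "").split(";") if s.strip()
            )
            rows.append(
                (
                    rec["name"].strip(),
                    rec["formula"].strip(),
                    int(rec["n_carboxy"]),
                    int(rec["n_phospho_monoester"]),
                    synonyms,
                )
            )
    return _build_registry(rows)


def resolve_species(
    name: str, registry: Mapping[str, LipidSpecies] | None = None
) -> LipidSpecies:
    """Resolve a panel entry: shorthand like ``FA(20:4)`` or a registry name."""
    try:
        return parse_lipid_shorthand(name)
    except LipidNameError:
        return registry_lookup(name, registry)
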
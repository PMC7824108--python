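"""Reproducibility statistics: CV, dilution-series linearity, and QC reports.

The validation design spikes authentic standards into buffer or pooled serum
at serial 2-fold dilutions (×1, ×2, ×4, ×8, ×16) with a few replicates per
level, then asks two questions per species: how repeatable is the peak area
within a level (CV%), and how linear is the response across levels (Pearson
correlation between relative concentration and mean area).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionDesign",
    "QCReport",
    "cv_percent",
    "dilution_linearity",
    "qc_report",
]


@dataclass(frozen=True)
class DilutionDesign:
    """Serial-dilution layout: fold-dilution levels and replicates per level."""

    levels: tuple[float, ...] = (1, 2, 4, 8, 16)
    replicates: int = 3
    matrix: str = "serum"  # "buffer" | "serum"

    def __post_init__(self) -> None:
        lv = tuple(float(x) for x in self.levels)
        if any(x < 1 for x in lv):
            raise ValueError("dilution levels must be >= 1")
        if list(lv) != sorted(set(lv)):
            raise ValueError("dilution levels must be strictly increasing")
        object.__setattr__(self, "levels", lv)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def condition_label(self, level: float) -> str:
        return f"x{level:g}"


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 × sd(n−1) / mean.

    Requires at least two non-missing values and a positive mean.
    """
    x = np.asarray([v for v in np.ravel(values) if np.isfinite(v)], dtype=float)
    if x.size < 2:
        raise ValueError(f"cv_percent needs >=2 values, got {x.size}")
    m = x.mean()
    if m <= 0:
        raise ValueError(f"cv_percent needs mean > 0, got {m}")
    return 100.0 * x.std(ddof=1) / m


def dilution_linearity(
    level_areas: Mapping[float, Sequence[float]],
    x_mode: str = "relative_concentration",
    pooled: bool = False,
) -> float:
    """Pearson correlation between dilution level and peak area.

    ``level_areas`` maps fold-dilution (1, 2, 4, ...) to replicate areas at
    that level. By default x is the relative concentration 1/fold — the axis
    on which a proportional response gives r = +1 — and y is the per-level
    replicate mean. ``x_mode='fold_dilution'`` correlates against the raw fold
    factor instead (the literal axis wording of spreadsheet-era reports, which
    makes a proportional response strongly *negative*); ``pooled=True``
    correlates all raw replicate points instead of level means.
    """
    if x_mode not in ("relative_concentration", "fold_dilution"):
        raise ValueError(f"unknown x_mode {x_mode!r}")
    levels = sorted(level_areas)
    xs, ys = [], []
    for lv in levels:
        areas = np.asarray(level_areas[lv], dtype=float)
        areas = areas[np.isfinite(areas)]
        if areas.size == 0:
            continue
        x = 1.0 / lv if x_mode == "relative_concentration" else float(lv)
        if pooled:
            xs.extend([x] * areas.size)
            ys.extend(areas.tolist())
        else:
            xs.append(x)
            ys.append(areas.mean())
    n_levels = len(set(xs))
    if n_levels < 3:
        raise ValueError(f"dilution_linearity needs >=3 levels with data, got {n_levels}")
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    if np.ptp(xs_a) == 0 or np.ptp(ys_a) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, _p = stats.pearsonr(xs_a, ys_a)
    return float(r)


@dataclass
class QCReport:
    """Per species × matrix QC table: CV% per level, linearity r, pass/fail."""

    cv_table: pd.DataFrame  # set_id, species, level, cv_percent, cv_pass
    linearity: pd.DataFrame  # set_id, species, correlation, r_pass
    cv_threshold: float
    r_threshold: float
    x_mode: str

    @property
    def all_pass(self) -> bool:
        return bool(self.cv_table["cv_pass"].all() and self.linearity["r_pass"].all())

    def flagged(self) -> pd.DataFrame:
        """Entries exceeding the CV threshold or under the correlation floor."""
        bad_cv = self.cv_table.loc[~self.cv_table["cv_pass"]].copy()
        bad_cv["reason"] = "cv"
        bad_r = self.linearity.loc[~self.linearity["r_pass"]].copy()
        bad_r["reason"] = "correlation"
        return pd.concat([bad_cv, bad_r], ignore_index=True)

    def summary_text(self) -> str:
        lines = [
            f"QC report (CV threshold {self.cv_threshold}%, "
            f"correlation floor {self.r_threshold}, x = {self.x_mode})",
            f"  CV cells: {len(self.cv_table)}  "
            f"(failing: {int((~self.cv_table['cv_pass']).sum())})",
            f"  linearity rows: {len(self.linearity)}  "
            f"(failing: {int((~self.linearity['r_pass']).sum())})",
            f"  overall: {'PASS' if self.all_pass else 'FAIL'}",
        ]
        return "\n".join(lines)


def qc_report(
    areas: pd.DataFrame,
    design: DilutionDesign,
    cv_threshold: float = 30.0,
    r_threshold: float = 0.94,
    x_mode: str = "relative_concentration",
) -> QCReport:
    """Build the per-species QC table from a dilution-series area table.

    The area table uses the standard long format with ``condition`` encoding
    the fold-dilution level as ``x1, x2, ...`` (as written by
    :func:`tmtlipid.simulate.simulate_dilution_series`); ``set_id`` carries
    the matrix. The default correlation floor 0.94 is the observed validation
    floor of the assay; the default CV ceiling is 30%.
    """
    expected = {design.condition_label(lv): lv for lv in design.levels}
    present = set(areas["condition"].astype(str).unique())
    unknown = present - set(expected)
    if unknown:
        raise ValueError(
            f"area table conditions {sorted(unknown)} not in design levels "
            f"{sorted(expected)}"
        )
    if len(present) < len(expected):
        missing = sorted(set(expected) - present)
        raise ValueError(f"area table lacks design levels: {missing}")

    df = areas.copy()
    df["level"] = df["condition"].astype(str).map(expected)

    cv_rows = []
    lin_rows = []
    for (set_id, species), grp in df.groupby(["set_id", "species"]):
        level_areas: dict[float, np.ndarray] = {}
        for lv, sub in grp.groupby("level"):
            vals = sub["area"].to_numpy(dtype=float)
            level_areas[float(lv)] = vals
            cv = cv_percent(vals) if np.isfinite(vals).sum() >= 2 else np.nan
            cv_rows.append(
                {
                    "set_id": set_id,
                    "species": species,
                    "level": float(lv),
                    "cv_percent": cv,
                    "cv_pass": bool(np.isnan(cv) or cv <= cv_threshold),
                }
            )
        r = dilution_linearity(level_areas, x_mode=x_mode)
        lin_rows.append(
            {
                "set_id": set_id,
                "species": species,
                "correlation": r,
                "r_pass": bool(r >= r_threshold),
            }
        )
    return QCReport(
        cv_table=pd.DataFrame(cv_rows),
        linearity=pd.DataFrame(lin_rows),
        cv_threshold=cv_threshold,
        r_threshold=r_threshold,
        x_mode=x_mode,
    )
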
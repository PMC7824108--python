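"""Bridging-channel relative quantification of sixplex reporter-area tables.

Every multiplexed set carries one channel loaded with a common pooled-QC
bridging sample. Dividing each channel's reporter area by the bridging
channel's area within the same run cancels everything multiplicative that the
run shares — injection amount, matrix effect, instrument drift — so ratios are
comparable across sets. Fold changes versus a reference condition/time are
then computed on these ratios (``bridge`` mode) or, for designs where the
reference lives in other runs and cross-run response stability must be
assumed, on raw areas (``raw`` mode).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AREA_COLUMNS",
    "read_area_table",
    "bridge_normalize",
    "relative_to_reference",
    "aggregate_replicates",
]

AREA_COLUMNS = ["set_id", "species", "channel", "replicate", "condition", "time_h", "area"]
_KEY = ["set_id", "species", "channel", "replicate"]


def _validate_area_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"area table missing columns: {missing}")
    df = df.copy()
    df["set_id"] = df["set_id"].astype(str)
    df["species"] = df["species"].astype(str)
    df["channel"] = df["channel"].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    df["condition"] = df["condition"].astype(str)
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["area"] = pd.to_numeric(df["area"])

    if (df["replicate"] < 1).any():
        raise ValueError("replicate indices must be >= 1")
    if (df["time_h"] < 0).any():
        raise ValueError("time_h must be >= 0")
    neg = df["area"] < 0
    if neg.any():
        bad = df.loc[neg].iloc[0]
        raise ValueError(
            f"negative area {bad['area']} for {bad['species']} "
            f"(set {bad['set_id']}, channel {bad['channel']})"
        )
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        bad = df.loc[dup, _KEY].iloc[0].to_dict()
        raise ValueError(f"duplicate (set, species, channel, replicate) key: {bad}")
    n_missing = int(df["area"].isna().sum())
    if n_missing:
        logger.warning("area table contains %d missing area values", n_missing)
    return df


def read_area_table(source) -> pd.DataFrame:
    """Read and validate a long-format reporter-area CSV.

    Expected columns: ``set_id, species, channel, replicate, condition,
    time_h, area``. Blank areas become missing values (warned); negative
    areas and duplicate keys are rejected.
    """
    df = pd.read_csv(source, dtype={"channel": str, "set_id": str})
    return _validate_area_frame(df)


def _bridge_label(design) -> str:
    """Accept a design mapping/object or a bare channel label."""
    if isinstance(design, str):
        return design
    if isinstance(design, dict):
        if "bridge_channel" in design:
            return str(design["bridge_channel"])
        # channel → role mapping
        bridges = [ch for ch, role in design.items() if role == "bridging"]
        if len(bridges) == 1:
            return str(bridges[0])
        raise ValueError(
            "design must name exactly one bridging channel "
            f"(got {bridges or 'none'})"
        )
    label = getattr(design, "bridge_channel", None)
    if label is None:
        raise ValueError("design lacks a bridging channel")
    return str(label)


def bridge_normalize(areas: pd.DataFrame, design) -> pd.DataFrame:
    """Divide every reporter area by its run's bridging-channel area.

    ``ratio[s,i,c,r] = area[s,i,c,r] / area[s,i,bridge,r]``, computed per
    (set, species, replicate) group. Groups whose bridging area is missing or
    zero yield missing ratios for all their channels (warned, never imputed).
    Multiplying all areas of a set by any positive constant leaves the result
    unchanged — the method's core guarantee.

    ``design`` is a bridging channel label, a dict with ``bridge_channel``,
    or a channel→role mapping containing exactly one ``"bridging"``.
    """
    bridge = _bridge_label(design)
    df = _validate_area_frame(areas)
    if not (df["channel"] == bridge).any():
        raise ValueError(f"bridging channel {bridge!r} absent from area table")

    bridge_areas = (
        df.loc[df["channel"] == bridge]
        .set_index(["set_id", "species", "replicate"])["area"]
        .rename("bridge_area")
    )
    out = df.join(bridge_areas, on=["set_id", "species", "replicate"])
    if out["bridge_area"].isna().any() and df.loc[df["channel"] == bridge, "area"].notna().all():
        # groups with no bridging record at all
        missing_groups = out.loc[out["bridge_area"].isna(), ["set_id", "species", "replicate"]]
        raise ValueError(
            "groups without a bridging-channel record: "
            f"{missing_groups.drop_duplicates().to_dict('records')[:3]}"
        )
    invalid = out["bridge_area"].isna() | (out["bridge_area"] == 0)
    if invalid.any():
        n_groups = out.loc[invalid, ["set_id", "species", "replicate"]].drop_duplicates()
        logger.warning(
            "bridging area missing or zero for %d group(s); their ratios are set missing",
            len(n_groups),
        )
    out["ratio_to_bridge"] = np.where(
        invalid, np.nan, out["area"] / out["bridge_area"]
    )
    return out.drop(columns="bridge_area")


def relative_to_reference(
    data: pd.DataFrame,
    reference: tuple[str, float],
    mode: str = "bridge",
) -> pd.DataFrame:
    """Fold changes per species versus a reference (condition, time_h).

    ``bridge`` mode divides bridging-normalized ratios by the per-species mean
    reference ratio; ``raw`` mode does the same on raw areas, which assumes the
    instrument response is stable across the runs being compared (a caveat
    logged at run time). Species whose reference cells are entirely missing
    are excluded with a warning. Missing values propagate; nothing is imputed.
    """
    if mode == "bridge":
        value_col = "ratio_to_bridge"
        if value_col not in data.columns:
            raise ValueError("bridge mode requires a bridge-normalized table "
                             "(run bridge_normalize first)")
    elif mode == "raw":
        value_col = "area"
        logger.warning(
            "raw mode assumes cross-run response stability; fold changes are "
            "not protected by the bridging sample"
        )
    else:
        raise ValueError(f"mode must be 'bridge' or 'raw', got {mode!r}")

    ref_condition, ref_time = reference
    df = data.copy()
    is_ref = (df["condition"] == str(ref_condition)) & (
        df["time_h"] == float(ref_time)
    )
    if not is_ref.any():
        raise ValueError(f"no rows match reference {reference!r}")

    ref_means = (
        df.loc[is_ref].groupby("species")[value_col].mean().rename("ref_mean")
    )
    dropped = []
    for sp in df["species"].unique():
        if sp not in ref_means.index or not np.isfinite(ref_means.get(sp, np.nan)):
            dropped.append(sp)
    if dropped:
        logger.warning(
            "species with entirely missing reference excluded: %s", dropped
        )
        df = df[~df["species"].isin(dropped)]
        ref_means = ref_means.drop(index=[s for s in dropped if s in ref_means.index])

    out = df.join(ref_means, on="species")
    out["fold_change"] = out[value_col] / out["ref_mean"]
    cols = ["set_id", "species", "channel", "replicate", "condition", "time_h", "fold_change"]
    return out[cols]


def aggregate_replicates(
    fold: pd.DataFrame,
    value_col: str = "fold_change",
    by: Sequence[str] = ("species", "condition", "time_h"),
) -> pd.DataFrame:
    """Per (species, condition, time) mean, SEM and replicate count.

    SEM uses the sample (n−1) standard deviation over √n; a single replicate
    yields a missing SEM rather than zero.
    """
    if value_col not in fold.columns:
        raise ValueError(f"column {value_col!r} not in table")
    g = fold.dropna(subset=[value_col]).groupby(list(by))[value_col]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan
    return out.drop(columns="sd")
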
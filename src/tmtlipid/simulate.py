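"""Synthetic sixplex SRM datasets with known ground truth.

The generator emulates the two study designs the quantification and QC code
exists for, without any instrument data:

* a **stability design** — six channels per run (five sample conditions plus a
  pooled-QC bridging channel), two incubation time points and a few
  replicates, with configurable true fold changes per species; and
* a **dilution-series design** — serial 2-fold dilutions of a standard mix in
  buffer and/or serum, expected area proportional to relative concentration.

Peak areas follow a multiplicative lognormal error model,

    area[s,i,c,r] = T[i,c] * S[s] * B[c] * R[i] * eps,

with per-set scale S (injection amount, matrix, drift), per-channel labeling
bias B (fixed per reagent channel — the one nuisance bridging does *not*
remove), per-species response R, and per-measurement noise eps. Every random
draw flows from the single config seed, so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tmtlipid.qc_stats import DilutionDesign

__all__ = [
    "SimulationConfig",
    "DEFAULT_CONDITIONS",
    "simulate_sixplex",
    "simulate_dilution_series",
    "recovery_metrics",
    "default_stability_folds",
]

#: Five pooled disease sera plus the pooled-QC bridge, as one sixplex set.
DEFAULT_CONDITIONS = ("alzheimer", "parkinson", "depression", "schizophrenia", "stroke")
CHANNEL_LABELS = ("126", "127", "128", "129", "130", "131")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the sixplex stability-design generator.

    ``true_fold`` maps ``(species, condition, time_h)`` to the true abundance
    relative to the bridging QC sample at time 0; unspecified cells default
    to 1. The bridging channel always carries the common QC-at-0h aliquot
    (true abundance 1 in every set). All sigmas are lognormal scale
    parameters; ``channel_bias_sigma`` defaults to 0 and is an optional
    stressor — a fixed per-channel labeling bias that bridging normalization
    cannot cancel.
    """

    species: tuple[str, ...]
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    bridge_condition: str = "QC"
    bridge_channel: str = "131"
    times: tuple[float, ...] = (0.0, 20.0)
    replicates: int = 3
    true_fold: Mapping[tuple[str, str, float], float] = field(default_factory=dict)
    set_effect_sigma: float = 0.5
    channel_bias_sigma: float = 0.0
    response_sigma: float = 0.5
    noise_sigma: float = 0.1
    base_area: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species list must be non-empty")
        if len(self.conditions) != 5:
            raise ValueError("exactly five sample conditions plus the bridge are required")
        for name, sig in (
            ("set_effect_sigma", self.set_effect_sigma),
            ("channel_bias_sigma", self.channel_bias_sigma),
            ("response_sigma", self.response_sigma),
            ("noise_sigma", self.noise_sigma),
        ):
            if sig < 0:
                raise ValueError(f"{name} must be >= 0, got {sig}")
        for key, t in self.true_fold.items():
            if t <= 0:
                raise ValueError(f"true abundance must be > 0: {key} -> {t}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def channel_map(self) -> dict[str, str]:
        """Channel label → condition; the last channel is the QC bridge."""
        mapping = dict(zip(CHANNEL_LABELS[:5], self.conditions))
        mapping[self.bridge_channel] = self.bridge_condition
        return mapping


def _lognormal(rng: np.random.Generator, sigma: float, size=None):
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_sixplex(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a stability-design area table and its aligned ground truth.

    One sixplex set (one LC/MS run) per (time, replicate). Returns
    ``(areas, truth)``: *areas* in the standard long format consumed by
    :func:`tmtlipid.quant.bridge_normalize`, *truth* row-aligned 1:1 with the
    realized true abundance, set effect, channel bias, response and noise of
    every record.
    """
    rng = np.random.default_rng(cfg.seed)
    species = list(cfg.species)
    ch_map = cfg.channel_map

    response = dict(zip(species, _lognormal(rng, cfg.response_sigma, len(species))))
    bias = dict(zip(CHANNEL_LABELS, _lognormal(rng, cfg.channel_bias_sigma, 6)))

    rows, truth_rows = [], []
    for time_h in cfg.times:
        for rep in range(1, cfg.replicates + 1):
            set_id = f"t{time_h:g}h_r{rep}"
            s_eff = float(_lognormal(rng, cfg.set_effect_sigma))
            for sp in species:
                for ch in CHANNEL_LABELS:
                    cond = ch_map[ch]
                    if ch == cfg.bridge_channel:
                        t_true = 1.0  # common QC-0h aliquot in every set
                    else:
                        t_true = float(
                            cfg.true_fold.get((sp, cond, float(time_h)), 1.0)
                        )
                    eps = float(_lognormal(rng, cfg.noise_sigma))
                    area = cfg.base_area * t_true * s_eff * bias[ch] * response[sp] * eps
                    rows.append(
                        {
                            "set_id": set_id,
                            "species": sp,
                            "channel": ch,
                            "replicate": rep,
                            "condition": cond,
                            "time_h": float(time_h)
                            if ch != cfg.bridge_channel
                            else 0.0,
                            "area": area,
                        }
                    )
                    truth_rows.append(
                        {
                            "set_id": set_id,
                            "species": sp,
                            "channel": ch,
                            "replicate": rep,
                            "condition": cond,
                            "time_h": float(time_h)
                            if ch != cfg.bridge_channel
                            else 0.0,
                            "true_fold": t_true,
                            "set_effect": s_eff,
                            "channel_bias": bias[ch],
                            "response": response[sp],
                            "noise": eps,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def default_stability_folds(
    species: Sequence[str],
    fold_20h: Mapping[str, float],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> dict[tuple[str, str, float], float]:
    """Convenience: apply one per-species 20 h fold change across all conditions.

    Mirrors the serum-stability picture — e.g. arachidonic acid released
    during incubation (fold > 1), diacyl phosphatidic acid hydrolyzed
    (fold < 1) — with condition-independent kinetics unless overridden.
    """
    out: dict[tuple[str, str, float], float] = {}
    for sp in species:
        f = float(fold_20h.get(sp, 1.0))
        for cond in conditions:
            out[(sp, cond, 20.0)] = f
    return out


def simulate_dilution_series(
    design: DilutionDesign,
    species: Sequence[str],
    noise_sigma: float = 0.1,
    matrices: Sequence[str] | None = None,
    base_area: float = 1e5,
    response_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a serial-dilution area table: expected area ∝ 1/fold-dilution.

    One ``set_id`` per matrix; ``condition`` encodes the level as ``x1, x2,
    ...`` and each level occupies its own reporter channel (126 upward), as
    when the serial dilutions are multiplexed into one labeled set. The same
    lognormal noise model applies; ground truth carries the expected
    (noise-free) area per record.
    """
    rng = np.random.default_rng(seed)
    if not species:
        raise ValueError("species list must be non-empty")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    matrices = list(matrices) if matrices is not None else [design.matrix]

    rows, truth_rows = [], []
    for matrix in matrices:
        response = dict(zip(species, _lognormal(rng, response_sigma, len(species))))
        for sp in species:
            for i, lv in enumerate(design.levels):
                expected = base_area * response[sp] / lv
                for rep in range(1, design.replicates + 1):
                    eps = float(_lognormal(rng, noise_sigma))
                    rows.append(
                        {
                            "set_id": matrix,
                            "species": sp,
                            "channel": str(126 + i),
                            "replicate": rep,
                            "condition": design.condition_label(lv),
                            "time_h": 0.0,
                            "area": expected * eps,
                        }
                    )
                    truth_rows.append(
                        {
                            "set_id": matrix,
                            "species": sp,
                            "condition": design.condition_label(lv),
                            "replicate": rep,
                            "level": lv,
                            "expected_area": expected,
                            "noise": eps,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def recovery_metrics(estimates: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-species error statistics of estimated versus true fold changes.

    ``estimates`` is a fold-change table (from
    :func:`tmtlipid.quant.relative_to_reference`); ``truth`` the ground-truth
    frame from :func:`simulate_sixplex`. Rows are matched on
    (set_id, species, channel, replicate); a key mismatch is an error, never
    silently dropped.
    """
    key = ["set_id", "species", "channel", "replicate"]
    for col in key + ["fold_change"]:
        if col not in estimates.columns:
            raise ValueError(f"estimates missing column {col!r}")
    for col in key + ["true_fold"]:
        if col not in truth.columns:
            raise ValueError(f"truth missing column {col!r}")
    est_keys = set(map(tuple, estimates[key].itertuples(index=False)))
    truth_keys = set(map(tuple, truth[key].itertuples(index=False)))
    if not est_keys <= truth_keys:
        missing = sorted(est_keys - truth_keys)[:3]
        raise ValueError(f"estimate keys absent from truth, e.g. {missing}")

    merged = estimates.merge(truth[key + ["true_fold"]], on=key, validate="one_to_one")
    merged["error"] = merged["fold_change"] - merged["true_fold"]
    g = merged.dropna(subset=["error"]).groupby("species")["error"]
    out = g.agg(
        bias="mean",
        rmse=lambda e: float(np.sqrt(np.mean(np.square(e)))),
        max_abs_error=lambda e: float(np.max(np.abs(e))),
        n="count",
    ).reset_index()
    return out
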
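"""Germination and seedling trait derivation from daily counts.

Thirteen traits per experimental unit, computed from ten days of newly
germinated seed counts N_1..N_10 (day i = T_i) and day-10 seedling
measurements:

==========  =====================================================
GP (%)      100 * sum(N_i) / seeds sown
GRI         mean daily germination percentage (see variants below)
CVG         100 * sum(N_i) / sum(N_i * T_i)  — velocity of germination
GI          sum((11 - i) * N_i)              — early germination weighting
MGT (d)     sum(T_i * N_i) / sum(N_i)        — mean germination time
SVI         GP * SL                          — seedling vigor
ShL, RL     shoot / root length (cm), measured
SL (cm)     ShL + RL
RSR         RL / ShL
SFW, SDW    fresh / dry weight (mg), measured
WCP (%)     100 * (SFW - SDW) / SFW
==========  =====================================================

GRI variants: the literature defines GRI as the average of daily germination
percentages G_1..G_10, but leaves open whether G_i is the *cumulative*
percentage reached by day i (default here) or the daily *increment*; the
increment reading collapses to GP/10. GI likewise appears both on a raw-count
and a per-seed-fraction scale; the fraction scale (0-10) matches the
magnitudes reported for barley screens and is the default.

Units with no germination get GP = GRI = GI = 0 but CVG and MGT are reported
missing: a zero there would read as instantaneous germination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .phenotypes import COUNT_COLUMNS, KEY_COLUMNS, validate_phenotypes

__all__ = [
    "TRAIT_NAMES",
    "germination_percentage",
    "germination_rate_index",
    "coefficient_of_velocity",
    "germination_index",
    "mean_germination_time",
    "seedling_vigor_index",
    "derive_seedling_traits",
    "compute_trait_table",
    "accession_treatment_means",
]

#: Output order of the thirteen derived traits.
TRAIT_NAMES = [
    "GP", "GRI", "CVG", "GI", "MGT", "SVI",
    "ShL", "RL", "SL", "RSR", "SFW", "SDW", "WCP",
]

_DAYS = np.arange(1, 11, dtype=float)


def _counts2d(counts) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(counts, dtype=float))
    if arr.shape[-1] != 10:
        raise ValueError("daily counts must have 10 entries (days 1..10)")
    return arr


def germination_percentage(counts, seeds_sown) -> np.ndarray:
    """GP: final germination as a percentage of seeds sown."""
    counts = _counts2d(counts)
    seeds = np.asarray(seeds_sown, dtype=float)
    if np.any(seeds <= 0):
        raise ValueError("seeds_sown must be > 0")
    return 100.0 * counts.sum(axis=1) / seeds


def germination_rate_index(counts, seeds_sown, variant: str = "cumulative") -> np.ndarray:
    """GRI: mean daily germination percentage over the 10-day test."""
    counts = _counts2d(counts)
    seeds = np.asarray(seeds_sown, dtype=float)
    daily_pct = 100.0 * counts / seeds[..., None]
    if variant == "cumulative":
        g = np.cumsum(daily_pct, axis=1)
    elif variant == "daily":
        g = daily_pct
    else:
        raise ValueError(f"unknown GRI variant {variant!r}")
    return g.mean(axis=1)


def coefficient_of_velocity(counts) -> np.ndarray:
    """CVG: 100 * sum(N_i) / sum(N_i * T_i); missing when nothing germinated."""
    counts = _counts2d(counts)
    total = counts.sum(axis=1)
    weighted = counts @ _DAYS
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 100.0 * total / weighted, np.nan)
    return out


def germination_index(counts, seeds_sown, scale: str = "fraction") -> np.ndarray:
    """GI: day-weighted germination, weight 10 for day 1 down to 1 for day 10."""
    counts = _counts2d(counts)
    weights = 11.0 - _DAYS
    raw = counts @ weights
    if scale == "fraction":
        return raw / np.asarray(seeds_sown, dtype=float)
    if scale == "count":
        return raw
    raise ValueError(f"unknown GI scale {scale!r}")


def mean_germination_time(counts) -> np.ndarray:
    """MGT: count-weighted mean germination day; missing when nothing germinated."""
    counts = _counts2d(counts)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, (counts @ _DAYS) / total, np.nan)


def seedling_vigor_index(gp, sl) -> np.ndarray:
    """SVI: germination percentage times total seedling length (% * cm)."""
    return np.asarray(gp, dtype=float) * np.asarray(sl, dtype=float)


def derive_seedling_traits(shl, rl, sfw, sdw):
    """Return (SL, RSR, WCP) from the day-10 seedling measurements.

    RSR is missing where shoot length is zero, WCP where fresh weight is zero.
    """
    shl = np.asarray(shl, dtype=float)
    rl = np.asarray(rl, dtype=float)
    sfw = np.asarray(sfw, dtype=float)
    sdw = np.asarray(sdw, dtype=float)
    sl = shl + rl
    with np.errstate(invalid="ignore", divide="ignore"):
        rsr = np.where(shl != 0, rl / shl, np.nan)
        wcp = np.where(sfw != 0, 100.0 * (sfw - sdw) / sfw, np.nan)
    return sl, rsr, wcp


def compute_trait_table(records: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Derive the 13-trait table, one row per accession x treatment x replicate.

    ``records`` is a validated phenotype frame (see :mod:`saltscan.phenotypes`).
    The GRI variant and GI scale are taken from ``config``.
    """
    config = config or PipelineConfig()
    records = validate_phenotypes(records)
    counts = records[COUNT_COLUMNS].to_numpy(dtype=float)
    seeds = records["seeds_sown"].to_numpy(dtype=float)

    out = records[KEY_COLUMNS].copy()
    out["GP"] = germination_percentage(counts, seeds)
    out["GRI"] = germination_rate_index(counts, seeds, config.gri_variant)
    out["CVG"] = coefficient_of_velocity(counts)
    out["GI"] = germination_index(counts, seeds, config.gi_count_scale)
    out["MGT"] = mean_germination_time(counts)
    sl, rsr, wcp = derive_seedling_traits(
        records["shoot_length_cm"], records["root_length_cm"],
        records["fresh_weight_mg"], records["dry_weight_mg"],
    )
    out["SVI"] = seedling_vigor_index(out["GP"], sl)
    out["ShL"] = records["shoot_length_cm"].to_numpy(dtype=float)
    out["RL"] = records["root_length_cm"].to_numpy(dtype=float)
    out["SL"] = sl
    out["RSR"] = rsr
    out["SFW"] = records["fresh_weight_mg"].to_numpy(dtype=float)
    out["SDW"] = records["dry_weight_mg"].to_numpy(dtype=float)
    out["WCP"] = wcp
    return out.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)


def accession_treatment_means(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per accession x treatment (missing values excluded)."""
    return (
        trait_table.groupby(["accession", "treatment"], sort=True)[TRAIT_NAMES]
        .mean()
        .reset_index()
    )
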
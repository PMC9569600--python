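"""Pipeline configuration.

A single :class:`PipelineConfig` object carries every tunable constant of the
screening analysis — the subsampling design of the cofactor search, the
family-wise error target, and the annotation windows — so that one YAML file
(or one object) reproduces a full run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

_GRI_VARIANTS = ("cumulative", "daily")
_GI_SCALES = ("fraction", "count")


@dataclass
class PipelineConfig:
    """Constants governing a screening run.

    Parameters
    ----------
    seed
        Root RNG seed; every stochastic step derives its stream from it.
    n_subsamples
        Number of 80/20 accession subsamples drawn during cofactor discovery.
    subsample_fraction
        Fraction of accessions placed in the training part of each subsample.
    alpha
        Family-wise error target for Bonferroni-corrected significance.
    flank_bp
        Half-width (bp) of the candidate-gene window around a significant SNP.
    qtl_merge_bp
        Maximum gap (bp) at which two significant SNPs on one chromosome are
        merged into one putative QTL region.
    maf_min
        Minor-allele-frequency floor applied before association analysis.
    gri_variant
        Germination-rate-index reading: ``"cumulative"`` averages the running
        cumulative germination percentage over the 10 days; ``"daily"``
        averages the daily increments.
    gi_count_scale
        Germination-index weighting basis: per-seed ``"fraction"`` (0–10
        scale) or raw ``"count"``.
    """

    seed: int = 0
    n_subsamples: int = 100
    subsample_fraction: float = 0.80
    alpha: float = 0.05
    flank_bp: int = 100_000
    qtl_merge_bp: int = 1_000_000
    maf_min: float = 0.0
    gri_variant: str = "cumulative"
    gi_count_scale: str = "fraction"

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("flank_bp", "qtl_merge_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.gri_variant not in _GRI_VARIANTS:
            raise ValueError(f"gri_variant must be one of {_GRI_VARIANTS}")
        if self.gi_count_scale not in _GI_SCALES:
            raise ValueError(f"gi_count_scale must be one of {_GI_SCALES}")
        if self.n_subsamples < 0:
            raise ValueError("n_subsamples must be >= 0")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a YAML mapping.

    Unknown keys raise rather than being silently dropped.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a YAML mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
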
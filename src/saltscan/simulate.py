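"""Synthetic inbred-panel generator for end-to-end testing of the pipeline.

The generator emulates a two-treatment (control vs 150 mM NaCl) germination
screen of an inbred barley-like panel: ~192 homozygous accessions genotyped
at a few thousand biallelic SNPs on 7 chromosomes, phenotyped in 3 replicate
boxes of 30 seeds over a 10-day test, with day-10 seedling measurements.

Genotypes carry linkage disequilibrium through a block copy-model: markers
come in blocks whose anchor column is drawn at a frequency sampled from the
MAF range; every other marker in the block copies its anchor with probability
``within_block_corr`` and is otherwise redrawn at the anchor frequency. The
expected squared correlation is ``c^2`` between anchor and copy and ``c^4``
between two copies, which is enough LD realism to exercise cofactor selection
while staying analytically checkable.

A latent salt-tolerance value per accession is the sum of a handful of
planted additive QTL effects and a polygenic normal term. It feeds the
phenotype model:

* a seed germinates with probability
  ``invlogit(intercept - slope * (salinity - tolerance))``;
* its germination day is ``clamp(round(Normal(mu, day_sd)), 1, 10)`` with
  ``mu = base_mean + salinity_delay * salinity - delay_slope * tolerance``;
* seedling measurements are ``mean * treatment_multiplier * (1 + cv * tol_z)``
  plus Gaussian noise whose SD is calibrated from the target broad-sense
  heritability (``sigma_e^2 = r * sigma_g^2 * (1 - h2) / h2`` with r the
  replicate count), unless an explicit noise SD is supplied.

Default measurement means and treatment multipliers are set to the scale of
published intermedium-spike barley screens (shoot ~10 cm control dropping
~37% under salt, dry weight *increasing* ~25% under salt, fresh weight
~291 mg dropping ~31%), so simulated relative salinity performance reproduces
the signature directions: negative for germination percentage, positive for
mean germination time and dry weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, _recode_major
from .phenotypes import COUNT_COLUMNS, validate_phenotypes

__all__ = [
    "PlantedQtl",
    "GermModelParams",
    "SimulationSpec",
    "SimulatedPanel",
    "simulate_genotypes",
    "simulate_latent_tolerance",
    "simulate_experiment",
    "simulate_panel",
]

_QTL_FRACTIONS = (0.08, 0.32, 0.58, 0.86)  # default planted-QTL positions
_QTL_EFFECTS = (0.8, 0.7, 0.6, 0.6)  # additive effects on the latent tolerance


@dataclass(frozen=True)
class PlantedQtl:
    """One planted additive QTL acting on the latent tolerance."""

    marker_index: int
    effect: float
    treatment: str = "both"  # both | control | salinity

    def __post_init__(self) -> None:
        if self.treatment not in ("both", "control", "salinity"):
            raise ValueError(f"bad QTL treatment {self.treatment!r}")


@dataclass(frozen=True)
class GermModelParams:
    """Germination and seedling measurement model parameters.

    Noise SDs left at ``None`` are derived from the simulation's target
    heritability; explicit values override that calibration.
    """

    base_mean_day_control: float = 3.0  # mean germination day, control (d)
    salinity_delay_d: float = 0.6  # added mean days under salinity
    tolerance_to_delay_slope: float = 0.3  # d earlier per latent SD
    day_sd: float = 0.8  # SD of the germination-day draw (d)
    germ_logit_intercept: float = 2.5
    germ_logit_slope: float = 1.2
    seeds_sown: int = 30
    # day-10 seedling measurement means under control and salinity multipliers
    shl_mean_cm: float = 10.2
    rl_mean_cm: float = 11.1
    sfw_mean_mg: float = 291.0
    sdw_mean_mg: float = 30.0
    shl_salinity_mult: float = 0.63
    rl_salinity_mult: float = 0.66
    sfw_salinity_mult: float = 0.69
    sdw_salinity_mult: float = 1.25  # dry weight rises under salinity
    genetic_cv: float = 0.15  # genetic SD of a measurement as fraction of its mean
    shl_noise_sd: float | None = None
    rl_noise_sd: float | None = None
    sfw_noise_sd: float | None = None
    sdw_noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.seeds_sown < 1:
            raise ValueError("seeds_sown must be >= 1")
        for name in ("day_sd", "shl_noise_sd", "rl_noise_sd", "sfw_noise_sd",
                     "sdw_noise_sd"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Panel design: genotype structure, planted QTL, phenotype model."""

    n_accessions: int = 192
    n_markers: int = 2000
    n_chromosomes: int = 7
    chrom_length_bp: int = 700_000_000
    ld_block_len: int = 10
    within_block_corr: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    qtl: tuple[PlantedQtl, ...] | None = None  # None -> default handful
    polygenic_sd: float = 1.0
    h2_target: float = 0.85
    n_replicates: int = 3
    germ: GermModelParams = field(default_factory=GermModelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError("h2_target must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not 0.0 <= self.within_block_corr <= 1.0:
            raise ValueError("within_block_corr must lie in [0, 1]")
        if self.qtl is None:
            object.__setattr__(self, "qtl", tuple(
                PlantedQtl(int(f * self.n_markers), eff)
                for f, eff in zip(_QTL_FRACTIONS, _QTL_EFFECTS)
            ))
        for q in self.qtl:
            if not 0 <= q.marker_index < self.n_markers:
                raise ValueError(f"QTL marker index {q.marker_index} out of range")

    def replace(self, **kwargs) -> "SimulationSpec":
        return replace(self, **kwargs)


def _chrom_sizes(n_markers: int, n_chromosomes: int) -> np.ndarray:
    base = n_markers // n_chromosomes
    sizes = np.full(n_chromosomes, base)
    sizes[: n_markers - base * n_chromosomes] += 1
    return sizes


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw an inbred 0/1 genotype panel with block-copy LD structure."""
    rng = rng or np.random.default_rng(spec.seed)
    n, m = spec.n_accessions, spec.n_markers
    calls = np.empty((n, m))
    lo, hi = spec.maf_range
    for start in range(0, m, spec.ld_block_len):
        stop = min(start + spec.ld_block_len, m)
        maf = rng.uniform(lo, hi)
        p_major = 1.0 - maf
        anchor = (rng.random(n) < p_major).astype(float)
        calls[:, start] = anchor
        for j in range(start + 1, stop):
            copy = rng.random(n) < spec.within_block_corr
            fresh = (rng.random(n) < p_major).astype(float)
            calls[:, j] = np.where(copy, anchor, fresh)

    sizes = _chrom_sizes(m, spec.n_chromosomes)
    chroms, positions, ids = [], [], []
    for c, size in enumerate(sizes, start=1):
        pos = np.sort(rng.choice(spec.chrom_length_bp, size=size, replace=False)) + 1
        chroms.extend([f"{c}H"] * size)
        positions.extend(int(p) for p in pos)
        ids.extend(f"{c}_{p}" for p in pos)
    markers = pd.DataFrame({"marker_id": ids, "chrom": chroms, "pos_bp": positions})
    # The sampled major allele can end up in the minority in a finite panel;
    # recode so the stored coding honours the 1 = observed-major convention.
    calls = _recode_major(calls.T).T
    return GenotypeMatrix([f"ACC{i:04d}" for i in range(n)], markers, calls)


def simulate_latent_tolerance(
    genotypes: GenotypeMatrix,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Latent salt tolerance per accession and treatment.

    latent = sum of applicable planted QTL effects (major-allele indicator
    times effect) plus one shared polygenic normal draw per accession.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = genotypes.n_accessions
    polygenic = rng.normal(0.0, spec.polygenic_sd, size=n)
    out = {}
    for treatment in ("control", "salinity"):
        latent = polygenic.copy()
        for q in spec.qtl:
            if q.treatment in ("both", treatment):
                x = np.nan_to_num(genotypes.calls[:, q.marker_index], nan=0.5)
                latent = latent + q.effect * x
        out[treatment] = latent
    return pd.DataFrame(out, index=pd.Index(genotypes.accessions, name="accession"))


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _noise_sd(explicit: float | None, genetic_sd: float, r: int, h2: float) -> float:
    if explicit is not None:
        return explicit
    return float(np.sqrt(r * genetic_sd**2 * (1.0 - h2) / h2))


def simulate_experiment(
    genotypes: GenotypeMatrix,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    latent: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate the full two-treatment, replicated germination experiment.

    Returns a validated phenotype frame (one row per accession x treatment x
    replicate). Records with zero germinated seeds have missing seedling
    measurements — there is nothing to measure on day 10.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if latent is None:
        latent = simulate_latent_tolerance(genotypes, spec, rng)
    g = spec.germ
    rows = []
    measures = (
        ("shoot_length_cm", g.shl_mean_cm, g.shl_salinity_mult, g.shl_noise_sd),
        ("root_length_cm", g.rl_mean_cm, g.rl_salinity_mult, g.rl_noise_sd),
        ("fresh_weight_mg", g.sfw_mean_mg, g.sfw_salinity_mult, g.sfw_noise_sd),
        ("dry_weight_mg", g.sdw_mean_mg, g.sdw_salinity_mult, g.sdw_noise_sd),
    )
    for treatment in ("control", "salinity"):
        sal = 1.0 if treatment == "salinity" else 0.0
        tol = latent[treatment].to_numpy()
        tol_z = _standardize(tol)
        p_germ = 1.0 / (1.0 + np.exp(-(g.germ_logit_intercept
                                       - g.germ_logit_slope * (sal - tol_z))))
        mu_day = (g.base_mean_day_control + g.salinity_delay_d * sal
                  - g.tolerance_to_delay_slope * tol_z)
        for i, accession in enumerate(genotypes.accessions):
            for rep in range(1, spec.n_replicates + 1):
                n_germ = rng.binomial(g.seeds_sown, p_germ[i])
                counts = np.zeros(10, dtype=int)
                if n_germ > 0:
                    days = np.clip(
                        np.rint(rng.normal(mu_day[i], g.day_sd, size=n_germ)), 1, 10
                    ).astype(int)
                    counts = np.bincount(days, minlength=11)[1:11]
                row = {
                    "accession": accession,
                    "treatment": treatment,
                    "replicate": rep,
                    "seeds_sown": g.seeds_sown,
                    **{col: int(c) for col, c in zip(COUNT_COLUMNS, counts)},
                }
                values = {}
                for col, mean, mult, explicit_sd in measures:
                    scale = mean * (mult if sal else 1.0)
                    genetic_sd = g.genetic_cv * scale
                    sd = _noise_sd(explicit_sd, genetic_sd, spec.n_replicates,
                                   spec.h2_target)
                    value = scale + genetic_sd * tol_z[i] + rng.normal(0.0, sd)
                    values[col] = max(value, 0.01 * scale)
                # day-10 measurements only exist when something germinated
                if n_germ == 0:
                    values = {col: np.nan for col, *_ in measures}
                elif values["dry_weight_mg"] > values["fresh_weight_mg"]:
                    values["dry_weight_mg"] = 0.99 * values["fresh_weight_mg"]
                row.update(values)
                rows.append(row)
    return validate_phenotypes(pd.DataFrame(rows))


def simulate_gene_models(
    spec: SimulationSpec,
    n_genes_per_chrom: int = 100,
    mean_len_bp: int = 3000,
    rng: np.random.Generator | None = None,
):
    """Synthetic gene models spread uniformly along the chromosomes.

    Provides a gene complement for exercising the candidate-gene window
    annotation; lengths are exponential around ``mean_len_bp``.
    """
    from .annotate import GeneModel

    rng = rng or np.random.default_rng(spec.seed + 1)
    genes = []
    for c in range(1, spec.n_chromosomes + 1):
        starts = np.sort(rng.choice(spec.chrom_length_bp - 10 * mean_len_bp,
                                    size=n_genes_per_chrom, replace=False)) + 1
        lengths = np.maximum(rng.exponential(mean_len_bp, n_genes_per_chrom), 200)
        for i, (start, length) in enumerate(zip(starts, lengths)):
            genes.append(
                GeneModel(
                    gene_id=f"GENE{c}H{i:04d}",
                    chrom=f"{c}H",
                    start=int(start),
                    end=int(start + length),
                    strand="+" if rng.random() < 0.5 else "-",
                    description=f"synthetic gene model {c}H-{i}",
                )
            )
    return genes


@dataclass
class SimulatedPanel:
    """A complete simulated study: genotypes, phenotypes, and the truth."""

    spec: SimulationSpec
    genotypes: GenotypeMatrix
    records: pd.DataFrame
    latent: pd.DataFrame
    truth: pd.DataFrame  # planted QTL marker ids, positions, effects

    def write(self, out_dir) -> None:
        from pathlib import Path

        from .genotypes import write_genotype_tsv
        from .phenotypes import write_phenotype_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotype_tsv(self.genotypes, out / "genotypes.tsv")
        write_phenotype_csv(self.records, out / "phenotypes.csv")
        self.truth.to_csv(out / "truth_qtl.tsv", sep="\t", index=False)


def simulate_panel(spec: SimulationSpec | None = None) -> SimulatedPanel:
    """Run the full generator with a single RNG stream from ``spec.seed``."""
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    genotypes = simulate_genotypes(spec, rng)
    latent = simulate_latent_tolerance(genotypes, spec, rng)
    records = simulate_experiment(genotypes, spec, rng, latent=latent)
    truth = pd.DataFrame(
        [
            {
                "marker_index": q.marker_index,
                "marker_id": genotypes.markers.loc[q.marker_index, "marker_id"],
                "chrom": genotypes.markers.loc[q.marker_index, "chrom"],
                "pos_bp": genotypes.markers.loc[q.marker_index, "pos_bp"],
                "effect": q.effect,
                "treatment": q.treatment,
            }
            for q in spec.qtl
        ]
    )
    return SimulatedPanel(spec, genotypes, records, latent, truth)
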
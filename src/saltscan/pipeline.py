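"""End-to-end orchestration: records -> traits -> indices -> stats -> GWAS -> genes.

All stage outputs are tab-separated tables with one header line; floats are
printed with 6 significant digits except p-values, which use scientific
notation. :func:`write_table` / :func:`read_table` implement that contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import gwas as _gwas
from .config import PipelineConfig
from .germination import TRAIT_NAMES, accession_treatment_means, compute_trait_table
from .genotypes import GenotypeMatrix
from .indices import STI_COLUMNS, build_sti_table, relative_performance_table
from .quantgen import correlation_matrix, ls_means, trait_statistics

logger = logging.getLogger(__name__)

__all__ = [
    "ResultsBundle",
    "write_table",
    "read_table",
    "phenotype_matrix",
    "run_pipeline",
]


def _is_p_column(name: str) -> bool:
    name = name.lower()
    return name.startswith("p_") or name.endswith("_p") or "_p_" in name or name == "p"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a stage table: TSV, 6 significant digits, p-values scientific."""
    out = df.reset_index() if index else df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            fmt = "{:.6e}" if _is_p_column(str(col)) else "{:.6g}"
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else fmt.format(v))
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def phenotype_matrix(trait_table: pd.DataFrame, sti_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Accession-indexed GWAS phenotypes: LS-means per trait x treatment + STIs.

    Column labels are ``<TRAIT>_<treatment>`` (for example ``GP_salinity``)
    and the stress-index names.
    """
    columns: dict[str, pd.Series] = {}
    for treatment in ("control", "salinity"):
        sub = trait_table[trait_table["treatment"] == treatment]
        for trait in TRAIT_NAMES:
            values = sub[trait]
            keep = values.notna()
            if keep.sum() == 0:
                continue
            columns[f"{trait}_{treatment}"] = ls_means(
                sub.loc[keep, "accession"].to_numpy(), values[keep].to_numpy()
            )
    out = pd.DataFrame(columns)
    if sti_table is not None:
        sti = sti_table.set_index("accession")[STI_COLUMNS]
        out = out.join(sti, how="outer")
    out.index.name = "accession"
    return out


@dataclass
class ResultsBundle:
    """All tables produced by one full screening run."""

    trait_table: pd.DataFrame
    trait_means: pd.DataFrame
    sti_table: pd.DataFrame
    relative_performance: pd.DataFrame
    anova_summary: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    gwas_scans: dict[str, pd.DataFrame] = field(default_factory=dict)
    cofactor_counts: pd.DataFrame | None = None
    significant: pd.DataFrame | None = None
    qtl_table: pd.DataFrame | None = None
    candidate_gene_table: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.trait_table, out / "trait_table.tsv")
        write_table(self.trait_means, out / "trait_means.tsv")
        write_table(self.sti_table, out / "sti_table.tsv")
        write_table(self.relative_performance, out / "relative_performance.tsv")
        write_table(self.anova_summary, out / "anova_summary.tsv")
        for label, corr in self.correlations.items():
            write_table(corr, out / f"correlation_{label}.tsv", index=True)
        for label, scan in self.gwas_scans.items():
            write_table(scan, out / f"gwas_scan_{label}.tsv")
        if self.cofactor_counts is not None:
            write_table(self.cofactor_counts, out / "cofactor_counts.tsv")
        if self.significant is not None:
            write_table(self.significant, out / "gwas_significant.tsv")
        if self.qtl_table is not None:
            write_table(self.qtl_table, out / "qtl_table.tsv")
        if self.candidate_gene_table is not None:
            write_table(self.candidate_gene_table, out / "candidate_genes.tsv")


def run_pipeline(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    genes: list[_annotate.GeneModel] | None = None,
    config: PipelineConfig | None = None,
    gwas_phenotypes: list[str] | None = None,
    **gwas_kwargs,
) -> ResultsBundle:
    """Execute every stage of the screening analysis.

    ``gwas_phenotypes`` restricts the scans to the named phenotype labels
    (default: every trait x treatment LS-mean and every stress index).
    """
    config = config or PipelineConfig()
    trait_table = compute_trait_table(records, config)
    means = accession_treatment_means(trait_table)
    sti = build_sti_table(means)
    rel = relative_performance_table(means, TRAIT_NAMES)
    anova = trait_statistics(trait_table)
    correlations = {}
    for treatment in ("control", "salinity"):
        r, _, _ = correlation_matrix(means[means["treatment"] == treatment])
        correlations[treatment] = r
    r_sti, _, _ = correlation_matrix(sti, STI_COLUMNS)
    correlations["sti"] = r_sti

    bundle = ResultsBundle(
        trait_table=trait_table,
        trait_means=means,
        sti_table=sti,
        relative_performance=rel,
        anova_summary=anova,
        correlations=correlations,
    )
    if genotypes is None:
        return bundle

    phenotypes = phenotype_matrix(trait_table, sti)
    if gwas_phenotypes is not None:
        missing = [p for p in gwas_phenotypes if p not in phenotypes.columns]
        if missing:
            raise ValueError(f"unknown GWAS phenotype labels: {missing}")
        phenotypes = phenotypes[gwas_phenotypes]
    results = _gwas.run_gwas(genotypes, phenotypes, config, **gwas_kwargs)

    sig_frames, count_frames = [], []
    for label, res in results.items():
        bundle.gwas_scans[label] = res.scan
        counts = res.cofactor_report.frame()
        counts.insert(0, "phenotype", label)
        count_frames.append(counts)
        sig = res.significant.copy()
        sig.insert(0, "phenotype", label)
        sig_frames.append(sig)
    bundle.cofactor_counts = pd.concat(count_frames, ignore_index=True)
    significant = pd.concat(sig_frames, ignore_index=True)
    bundle.significant = significant.sort_values(
        ["phenotype", "chrom", "pos_bp"], kind="stable"
    ).reset_index(drop=True)

    bundle.qtl_table = _annotate.merge_snps_to_qtl(bundle.significant, config.qtl_merge_bp)
    if genes is not None:
        bundle.candidate_gene_table = _annotate.candidate_genes(
            bundle.significant, genes, config.flank_bp
        )
    return bundle
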
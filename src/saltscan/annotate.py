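"""Summarise significant SNPs into putative QTL and annotate candidate genes.

Significant markers of one trait are clustered into putative QTL regions by
single-linkage: two markers join when they share a chromosome and lie within
``qtl_merge_bp`` of each other. Candidate genes are all gene models whose
interval intersects a window of ``+/- flank_bp`` around a significant SNP
(1-based inclusive coordinates throughout, matching GFF3 and the marker map);
a gene containing the SNP reports distance 0, otherwise the distance to the
nearer gene edge is reported together with whether the gene lies upstream
(gene before the SNP in chromosome coordinates) or downstream. Strand never
affects hit status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "read_gff3_genes",
    "write_gff3",
    "merge_snps_to_qtl",
    "candidate_genes",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval from GFF3 (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Uses an in-memory gffutils database; the ``ID`` attribute names the gene
    and ``description`` (or ``Note``) supplies the functional annotation.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        desc = feat.attributes.get("description", feat.attributes.get("Note", [""]))[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                description=desc,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene features as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            attrs = f"ID={gene.gene_id}"
            if gene.description:
                attrs += f";description={gene.description}"
            fh.write(
                f"{gene.chrom}\tsaltscan\tgene\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )


def merge_snps_to_qtl(significant: pd.DataFrame, qtl_merge_bp: int) -> pd.DataFrame:
    """Single-linkage merging of significant SNPs into putative QTL regions.

    ``significant`` needs columns ``marker_id``, ``chrom``, ``pos_bp``,
    ``p_raw``, ``estimate`` and optionally ``phenotype``. Markers of the same
    phenotype and chromosome merge when consecutive positions are within
    ``qtl_merge_bp``. Each region reports its member markers, interval, and
    the lead marker (smallest raw p, ties by position).
    """
    df = significant.copy()
    if "phenotype" not in df.columns:
        df["phenotype"] = ""
    regions = []
    for (phen, chrom), group in df.groupby(["phenotype", "chrom"], sort=True):
        group = group.sort_values(["pos_bp", "marker_id"], kind="stable")
        cluster: list[pd.Series] = []
        for _, row in group.iterrows():
            if cluster and row["pos_bp"] - cluster[-1]["pos_bp"] > qtl_merge_bp:
                regions.append(_close_region(phen, chrom, cluster))
                cluster = []
            cluster.append(row)
        if cluster:
            regions.append(_close_region(phen, chrom, cluster))
    out = pd.DataFrame(regions)
    if len(out):
        out = out.sort_values(["phenotype", "chrom", "start_bp"], kind="stable")
    return out.reset_index(drop=True)


def _close_region(phenotype, chrom, members: list[pd.Series]) -> dict:
    frame = pd.DataFrame(members)
    lead = frame.sort_values(["p_raw", "pos_bp"], kind="stable").iloc[0]
    return {
        "phenotype": phenotype,
        "chrom": chrom,
        "start_bp": int(frame["pos_bp"].min()),
        "end_bp": int(frame["pos_bp"].max()),
        "n_markers": len(frame),
        "member_markers": ",".join(frame["marker_id"].astype(str)),
        "lead_marker": lead["marker_id"],
        "lead_pos_bp": int(lead["pos_bp"]),
        "lead_p_raw": float(lead["p_raw"]),
        "lead_estimate": float(lead["estimate"]),
    }


def _gene_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # interval tree is half-open; +1 makes the GFF3 end inclusive
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end + 1, gene)
    return trees


def candidate_genes(
    markers: pd.DataFrame,
    genes: list[GeneModel],
    flank_bp: int,
) -> pd.DataFrame:
    """Genes intersecting the ±flank_bp window around each significant SNP.

    ``markers`` needs columns ``marker_id``, ``chrom``, ``pos_bp`` (and
    optionally ``phenotype``). Returns one row per (marker, gene) hit with
    the spatial relation (``contains_snp``, ``upstream`` = gene entirely
    before the SNP, ``downstream`` = gene entirely after) and the distance in
    bp to the nearer gene edge (0 when containing).
    """
    trees = _gene_trees(genes)
    rows = []
    for _, row in markers.iterrows():
        chrom, pos = row["chrom"], int(row["pos_bp"])
        tree = trees.get(chrom)
        if tree is None:
            logger.warning("chromosome %r absent from gene models; no hits", chrom)
            continue
        for iv in sorted(tree.overlap(pos - flank_bp, pos + flank_bp + 1)):
            gene: GeneModel = iv.data
            if gene.start <= pos <= gene.end:
                relation, distance = "contains_snp", 0
            elif gene.end < pos:
                relation, distance = "upstream", pos - gene.end
            else:
                relation, distance = "downstream", gene.start - pos
            hit = {
                "marker_id": row["marker_id"],
                "chrom": chrom,
                "pos_bp": pos,
                "gene_id": gene.gene_id,
                "gene_start": gene.start,
                "gene_end": gene.end,
                "strand": gene.strand,
                "description": gene.description,
                "relation": relation,
                "distance_bp": distance,
            }
            if "phenotype" in row.index:
                hit["phenotype"] = row["phenotype"]
            rows.append(hit)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.drop_duplicates(subset=["marker_id", "gene_id"] +
                                  (["phenotype"] if "phenotype" in out.columns else []))
        out = out.sort_values(["chrom", "pos_bp", "gene_start"], kind="stable")
    return out.reset_index(drop=True)
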
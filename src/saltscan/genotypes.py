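"""Genotype matrix container and readers.

The panel is inbred, so every marker is treated as biallelic with homozygous
calls only. Calls are stored as a major-allele indicator (1 = homozygous for
the major allele, 0 = homozygous minor, NaN = missing), which fixes the sign
convention of downstream association estimates: an effect is the effect of
carrying the major allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "read_genotypes", "write_genotype_tsv"]

MAP_COLUMNS = ["marker_id", "chrom", "pos_bp"]


@dataclass
class GenotypeMatrix:
    """Accessions x markers indicator matrix with its marker map.

    Attributes
    ----------
    accessions
        Accession identifiers, one per matrix row.
    markers
        Marker map with columns ``marker_id``, ``chrom``, ``pos_bp`` in file
        order; ``map_sorted`` records whether that order is (chrom, pos)
        sorted.
    calls
        ``(n_accessions, n_markers)`` float array; 1 = homozygous major
        allele, 0 = homozygous minor allele, NaN = missing.
    """

    accessions: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    map_sorted: bool = field(default=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.accessions), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )
        missing = [c for c in MAP_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker map lacks columns: {missing}")
        self.map_sorted = bool(
            self.markers.sort_values(["chrom", "pos_bp"], kind="stable")
            .index.equals(self.markers.index)
        )

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calls)

    def major_allele_frequency(self) -> np.ndarray:
        """Observed frequency of the major-allele indicator per marker.

        By construction of the coding this is >= 0.5 wherever the coding was
        derived from the data itself.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0)

    def is_monomorphic(self) -> np.ndarray:
        freq = self.major_allele_frequency()
        return ~np.isfinite(freq) | (freq == 0.0) | (freq == 1.0)

    def subset_accessions(self, keep: list[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accessions)}
        rows = [index[a] for a in keep]
        return GenotypeMatrix(list(keep), self.markers.copy(), self.calls[rows])


def _recode_major(raw: np.ndarray) -> np.ndarray:
    """Recode a (markers x accessions) 0/1/NaN array so 1 is the major allele.

    ``raw`` is an arbitrary-orientation indicator (e.g. 1 = allele 'A' or
    1 = REF). Markers where allele 1 has observed frequency < 0.5 are flipped;
    exact ties keep the incoming orientation.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(raw, axis=1)
    flip = freq < 0.5
    out = raw.copy()
    out[flip] = 1.0 - out[flip]
    return out


def _read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV lacks columns: {missing}")
    accessions = [c for c in df.columns if c not in MAP_COLUMNS]
    if not accessions:
        raise ValueError("genotype TSV has no accession columns")
    allele = df[accessions].to_numpy(dtype=object)
    raw = np.full(allele.shape, np.nan)
    raw[allele == "A"] = 1.0
    raw[allele == "B"] = 0.0
    bad = ~np.isin(allele, ["A", "B", "NA"]) & ~pd.isna(allele)
    if bad.any():
        values = sorted({str(v) for v in allele[bad.nonzero()]})
        raise ValueError(f"genotype TSV contains calls outside {{A, B, NA}}: {values}")
    calls = _recode_major(raw).T
    markers = df[MAP_COLUMNS].copy()
    markers["pos_bp"] = markers["pos_bp"].astype(int)
    return GenotypeMatrix(accessions, markers, calls)


def _read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, map_rows = [], []
    n_multi = n_het = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # genotypes: per sample [allele1, allele2, phased]; haploid gives one allele
        row = np.full(len(accessions), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                continue
            if len(set(alleles)) > 1:
                n_het += 1
                continue
            row[i] = 1.0 if alleles[0] == 0 else 0.0  # 1 = REF before recoding
        rows.append(row)
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}"
        map_rows.append((vid, variant.CHROM, variant.POS))
    if n_multi:
        logger.warning("skipped %d multi-allelic VCF sites", n_multi)
    if n_het:
        logger.warning(
            "set %d heterozygous VCF calls to missing (inbred panel assumption)", n_het
        )
    if not rows:
        raise ValueError(f"no usable biallelic sites in {path}")
    raw = np.vstack(rows)
    markers = pd.DataFrame(map_rows, columns=MAP_COLUMNS)
    return GenotypeMatrix(accessions, markers, _recode_major(raw).T)


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from the TSV dialect or a VCF.

    TSV dialect: one row per marker with columns ``marker_id``, ``chrom``,
    ``pos_bp`` followed by one column per accession holding ``A``/``B``/``NA``.
    VCF: biallelic sites with haploid or homozygous diploid calls;
    heterozygous calls become missing with a logged warning, multi-allelic
    sites are skipped with a logged count.
    """
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {format!r} (expected 'tsv' or 'vcf')")


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect (A = major allele, B = minor, NA = missing)."""
    allele = np.where(np.isnan(gm.calls.T), "NA", np.where(gm.calls.T == 1.0, "A", "B"))
    out = gm.markers.copy()
    for j, acc in enumerate(gm.accessions):
        out[acc] = allele[:, j]
    out.to_csv(path, sep="\t", index=False)
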
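"""Multi-locus association scan with resampling-based cofactor selection.

The scan follows the multiple-linear-regression GWAS scheme used for
moderately sized inbred panels:

1. *Cofactor discovery.* Repeated subsamples (default 100) each hold out 20%
   of the accessions. Within the training 80%, markers are ranked by a greedy
   forward selection under the Schwarz Bayesian Criterion,

       SBC = n * ln(RSS / n) + k * ln(n),

   with k the parameter count including the intercept. The prefix of the
   forward path with the smallest mean squared prediction error on the
   held-out 20% is kept, and every marker in it scores one selection. Markers
   selected in two or more subsamples become *potential cofactors*.
2. *Final cofactors.* Forward SBC selection over the potential cofactors on
   the full data; the entry order is retained.
3. *Scan.* Every marker is tested in the model
   ``y ~ intercept + cofactors (entry order) + marker`` with the marker
   entered last: its sequential (type-I) F-test gives the raw p-value, the
   sequential sum of squares over the corrected total gives the partial R²,
   and its coefficient is the additive effect of the major allele. A marker
   that is itself a cofactor (or numerically collinear with one) is tested
   with that cofactor removed from the conditioning set.
4. *Multiple testing.* Bonferroni: p_bonf = min(1, m * p_raw) with m the
   number of markers scanned; significance at p_bonf < alpha.

No kinship or population-structure correction is applied; the scheme relies
on the selected cofactors to absorb background genetic effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PreparedData",
    "CofactorReport",
    "GWASResults",
    "MultiLocusGWAS",
    "prepare",
    "forward_select_sbc",
    "subsample_cofactor_scan",
    "final_cofactors",
    "snp_scan",
    "bonferroni",
    "run_gwas",
]

_P_FLOOR = np.finfo(float).tiny  # reported p-values stay in (0, 1]
_COLLINEAR_TOL = 1e-8  # 1 - r^2 below this counts as collinear with cofactors


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class PreparedData:
    """Analysis-ready intersection of genotypes and one phenotype."""

    accessions: list[str]
    markers: pd.DataFrame  # marker_id, chrom, pos_bp of surviving markers
    X: np.ndarray  # (n, m) imputed major-allele indicators
    y: np.ndarray  # (n,) phenotype values
    m: int  # Bonferroni denominator = surviving marker count
    n_removed_monomorphic: int = 0
    n_removed_maf: int = 0
    n_removed_missing: int = 0

    @property
    def n(self) -> int:
        return len(self.y)


def prepare(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    config: PipelineConfig | None = None,
    max_missing_rate: float = 0.2,
) -> PreparedData:
    """Intersect accessions, filter markers, impute missing calls.

    Markers are dropped when monomorphic, when their minor-allele frequency
    falls below ``config.maf_min``, or when their missing rate exceeds
    ``max_missing_rate``; surviving missing calls are imputed to the marker's
    observed major-allele-frequency mean. The surviving marker count becomes
    the Bonferroni denominator ``m``.
    """
    config = config or PipelineConfig()
    phenotype = phenotype.dropna()
    shared = [a for a in genotypes.accessions if a in set(phenotype.index)]
    if len(shared) < 20:
        raise ValueError(
            f"only {len(shared)} accessions shared between genotypes and "
            "phenotype; at least 20 required"
        )
    gm = genotypes.subset_accessions(shared)
    calls = gm.calls
    missing = np.isnan(calls)
    miss_rate = missing.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    mono = ~np.isfinite(freq) | (maf == 0.0)
    low_maf = ~mono & (maf < config.maf_min)
    high_miss = ~mono & ~low_maf & (miss_rate > max_missing_rate)
    keep = ~(mono | low_maf | high_miss)
    if not keep.any():
        raise ValueError("no markers survive filtering")
    logger.info(
        "marker filtering: %d monomorphic, %d below MAF %.3g, %d above missing rate %.2f; %d retained",
        int(mono.sum()), int(low_maf.sum()), config.maf_min,
        int(high_miss.sum()), max_missing_rate, int(keep.sum()),
    )
    X = calls[:, keep].copy()
    col_mean = freq[keep]
    miss = np.isnan(X)
    if miss.any():
        X[miss] = np.broadcast_to(col_mean, X.shape)[miss]
    return PreparedData(
        accessions=shared,
        markers=gm.markers.loc[keep].reset_index(drop=True),
        X=X,
        y=phenotype.loc[shared].to_numpy(dtype=float),
        m=int(keep.sum()),
        n_removed_monomorphic=int(mono.sum()),
        n_removed_maf=int(low_maf.sum()),
        n_removed_missing=int(high_miss.sum()),
    )


# ---------------------------------------------------------------------------
# forward selection under SBC


def _sbc(n: int, rss: float, k: int) -> float:
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + k * np.log(n)


def _forward_path(
    Xc: np.ndarray,
    yc: np.ndarray,
    max_terms: int,
    singular_tol: float = 1e-10,
):
    """Greedy forward SBC selection on centered data via Gram-Schmidt.

    Returns ``(selected, sbc_path, rss_path)`` where ``selected`` are column
    indices in entry order and the paths include the intercept-only model at
    position 0.
    """
    n = Xc.shape[0]
    Xw = Xc.copy()
    yw = yc.copy()
    colnorm = np.einsum("ij,ij->j", Xw, Xw)
    norm0 = np.maximum(colnorm, 1.0)
    rss = float(yw @ yw)
    rss0 = max(rss, 1.0)
    k = 1
    sbc = _sbc(n, rss, k)
    selected: list[int] = []
    sbc_path = [sbc]
    rss_path = [rss]

    while len(selected) < max_terms and n > k + 1:
        proj = Xw.T @ yw
        with np.errstate(invalid="ignore", divide="ignore"):
            ss = np.where(colnorm > singular_tol * norm0, proj**2 / colnorm, -np.inf)
        j = int(np.argmax(ss))  # ties resolve to the smallest column index
        if not np.isfinite(ss[j]):
            break
        rss_new = max(rss - ss[j], 0.0)
        sbc_new = _sbc(n, rss_new, k + 1)
        if sbc_new >= sbc:
            break
        q = Xw[:, j] / np.sqrt(colnorm[j])
        gamma = Xw.T @ q
        Xw -= np.outer(q, gamma)
        colnorm = np.maximum(colnorm - gamma**2, 0.0)
        colnorm[j] = 0.0
        yw -= q * float(q @ yw)
        selected.append(j)
        rss = rss_new
        k += 1
        sbc = sbc_new
        sbc_path.append(sbc)
        rss_path.append(rss)
        if rss <= rss0 * 1e-12:
            break
    return selected, np.array(sbc_path), np.array(rss_path)


def forward_select_sbc(
    X: np.ndarray,
    y: np.ndarray,
    max_terms: int | None = None,
    candidates: np.ndarray | None = None,
):
    """Forward stepwise selection minimising the Schwarz Bayesian Criterion.

    Starts from the intercept-only model; at each step the marker giving the
    lowest SBC is added (ties broken by smaller marker index, numerically
    singular candidates skipped); stops when no addition lowers SBC or
    ``max_terms`` is reached.

    Returns ``(selected, sbc_path)``: global column indices in entry order and
    the SBC value after each model size (position 0 = intercept only).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if max_terms is None:
        max_terms = min(n // 10, 50)
    if candidates is None:
        candidates = np.arange(X.shape[1])
    candidates = np.asarray(candidates, dtype=int)
    Xc = X[:, candidates] - X[:, candidates].mean(axis=0)
    yc = y - y.mean()
    local, sbc_path, _ = _forward_path(Xc, yc, max_terms)
    return [int(candidates[j]) for j in local], sbc_path


# ---------------------------------------------------------------------------
# subsampling cofactor discovery


@dataclass
class CofactorReport:
    """Selection counts across subsamples and the resulting cofactor sets."""

    marker_ids: pd.Series  # all scanned marker ids
    counts: np.ndarray  # selections per marker across subsamples
    n_subsamples: int
    final: list[int] = field(default_factory=list)  # entry-ordered final cofactors

    @property
    def potential(self) -> np.ndarray:
        """Indices of markers selected more than once across subsamples."""
        return np.flatnonzero(self.counts >= 2)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"marker_id": self.marker_ids, "selection_count": self.counts}
        )
        df["potential_cofactor"] = df["selection_count"] >= 2
        df["final_cofactor"] = False
        df["entry_order"] = -1
        for order, idx in enumerate(self.final):
            df.loc[idx, "final_cofactor"] = True
            df.loc[idx, "entry_order"] = order
        return df


def _holdout_mse_path(X_train, y_train, X_test, y_test, path: list[int]) -> np.ndarray:
    """Held-out MSE of every prefix of a forward path (prefix 0 = mean only)."""
    mses = np.empty(len(path) + 1)
    mean = y_train.mean()
    mses[0] = float(np.mean((y_test - mean) ** 2))
    for p in range(1, len(path) + 1):
        cols = path[:p]
        design = np.column_stack([np.ones(len(y_train)), X_train[:, cols]])
        coef, *_ = np.linalg.lstsq(design, y_train, rcond=None)
        pred = np.column_stack([np.ones(len(y_test)), X_test[:, cols]]) @ coef
        mses[p] = float(np.mean((y_test - pred) ** 2))
    return mses


def subsample_cofactor_scan(
    X: np.ndarray,
    y: np.ndarray,
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
    prefilter_top: int | None = 500,
    max_terms: int | None = None,
    marker_ids: pd.Series | None = None,
) -> CofactorReport:
    """Count marker selections over repeated 80/20 accession subsamples.

    Each round draws ``subsample_fraction`` of the accessions without
    replacement, runs forward SBC selection on that training part (optionally
    restricted to the ``prefilter_top`` markers by marginal F within the
    training data), and keeps the forward-path prefix with the lowest mean
    squared prediction error on the held-out accessions. Every marker of the
    kept prefix scores one selection; markers with count >= 2 are flagged as
    potential cofactors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    rng = rng or np.random.default_rng(config.seed)
    counts = np.zeros(m, dtype=int)
    n_train = int(round(config.subsample_fraction * n))
    n_train = min(max(n_train, 2), n - 1)
    for _ in range(config.n_subsamples):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        Xtr, ytr = X[train], y[train]
        candidates = np.arange(m)
        if prefilter_top is not None and prefilter_top < m:
            Xc = Xtr - Xtr.mean(axis=0)
            yc = ytr - ytr.mean()
            colnorm = np.einsum("ij,ij->j", Xc, Xc)
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(colnorm > 0, (Xc.T @ yc) ** 2 / colnorm, -np.inf)
            candidates = np.sort(np.argpartition(score, -prefilter_top)[-prefilter_top:])
        path, _ = forward_select_sbc(Xtr, ytr, max_terms=max_terms, candidates=candidates)
        mses = _holdout_mse_path(Xtr, ytr, X[test], y[test], path)
        best = int(np.argmin(mses))  # ties favour the smaller model
        counts[path[:best]] += 1
    ids = marker_ids if marker_ids is not None else pd.Series(
        [f"marker_{i}" for i in range(m)]
    )
    return CofactorReport(marker_ids=ids.reset_index(drop=True), counts=counts,
                          n_subsamples=config.n_subsamples)


def final_cofactors(
    X: np.ndarray,
    y: np.ndarray,
    potential: np.ndarray,
    max_terms: int | None = None,
) -> list[int]:
    """Forward SBC selection over the potential cofactors on the full data."""
    if len(potential) == 0:
        return []
    selected, _ = forward_select_sbc(X, y, max_terms=max_terms,
                                     candidates=np.asarray(potential, dtype=int))
    return selected


# ---------------------------------------------------------------------------
# sequential scan and multiple testing


def _residualize(design_cols: list[np.ndarray], n: int):
    """Orthonormal basis of [1, design_cols] via QR."""
    mat = np.column_stack([np.ones(n)] + design_cols)
    q, _ = np.linalg.qr(mat)
    return q


def _seq_test(xc_norm2, x_res, y_res, n, n_params_before):
    """Sequential F-test of one marker entered last.

    ``n_params_before`` counts intercept + conditioning cofactors.
    """
    res_norm2 = float(x_res @ x_res)
    if xc_norm2 <= 0 or res_norm2 <= _COLLINEAR_TOL * xc_norm2:
        return None  # collinear with the conditioning set
    proj = float(x_res @ y_res)
    ss = proj**2 / res_norm2
    estimate = proj / res_norm2
    rss_before = float(y_res @ y_res)
    rss_after = max(rss_before - ss, 0.0)
    df_resid = n - n_params_before - 1
    if df_resid <= 0:
        return None
    if rss_after <= 0:
        f = np.inf
    else:
        f = ss / (rss_after / df_resid)
    p = float(stats.f.sf(f, 1, df_resid)) if np.isfinite(f) else 0.0
    return estimate, ss, max(p, _P_FLOOR)


def snp_scan(
    X: np.ndarray,
    y: np.ndarray,
    cofactors: list[int],
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test every marker entered last after the cofactors (type-I F-tests).

    Returns one row per marker with the major-allele effect estimate, the
    sequential partial R² (percent of the corrected total sum of squares),
    the raw p-value and its -log10. Markers that are cofactors themselves, or
    numerically collinear with one, are tested with the offending cofactor
    dropped from the conditioning set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    cofactors = list(cofactors)
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    Xc = X - X.mean(axis=0)
    xc_norm2 = np.einsum("ij,ij->j", Xc, Xc)

    q = _residualize([X[:, c] for c in cofactors], n)
    y_res = y - q @ (q.T @ y)
    X_res = X - q @ (q.T @ X)
    res_norm2 = np.einsum("ij,ij->j", X_res, X_res)
    proj = X_res.T @ y_res
    rss_before = float(y_res @ y_res)
    n_params = 1 + len(cofactors)
    df_resid = n - n_params - 1

    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.where(res_norm2 > 0, proj**2 / res_norm2, 0.0)
        estimate = np.where(res_norm2 > 0, proj / res_norm2, np.nan)
    rss_after = np.maximum(rss_before - ss, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(rss_after > 0, ss / (rss_after / max(df_resid, 1)), np.inf)
    p = np.where(np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 0.0), 1,
                                            max(df_resid, 1)), 0.0)
    p = np.maximum(p, _P_FLOOR)

    valid = df_resid > 0
    collinear = (xc_norm2 <= 0) | (res_norm2 <= _COLLINEAR_TOL * xc_norm2)
    is_cof = np.zeros(m, dtype=bool)
    is_cof[cofactors] = True

    # Re-test collinear markers (incl. the cofactors themselves) against a
    # reduced conditioning set. A cofactor's own test is the sequential
    # (type-I) test at its entry position, i.e. given only the cofactors
    # entered before it; a non-cofactor collinear with the set drops the
    # cofactor it is most correlated with.
    for j in np.flatnonzero(collinear):
        if xc_norm2[j] <= 0:
            estimate[j], ss[j], p[j] = np.nan, np.nan, np.nan
            continue
        if is_cof[j]:
            cond = cofactors[: cofactors.index(j)]
        else:
            cors = [
                abs(float(Xc[:, j] @ Xc[:, c]))
                / np.sqrt(max(xc_norm2[j] * xc_norm2[c], _P_FLOOR))
                for c in cofactors
            ]
            drop = cofactors[int(np.argmax(cors))] if cofactors else None
            cond = [c for c in cofactors if c != drop]
        q2 = _residualize([X[:, c] for c in cond], n)
        y2 = y - q2 @ (q2.T @ y)
        x2 = X[:, j] - q2 @ (q2.T @ X[:, j])
        out = _seq_test(xc_norm2[j], x2, y2, n, 1 + len(cond))
        if out is None:
            estimate[j], ss[j], p[j] = np.nan, np.nan, np.nan
        else:
            estimate[j], ss[j], p[j] = out

    if markers is None:
        markers = pd.DataFrame(
            {
                "marker_id": [f"marker_{i}" for i in range(m)],
                "chrom": ["0"] * m,
                "pos_bp": np.arange(m),
            }
        )
    rows = markers.reset_index(drop=True).copy()
    rows["estimate"] = estimate
    rows["partial_r2"] = 100.0 * ss / ss_total if ss_total > 0 else np.nan
    rows["p_raw"] = np.where(valid & np.isfinite(p), p, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rows["neg_log10_p"] = -np.log10(rows["p_raw"])
    rows["is_cofactor"] = is_cof
    return rows


def bonferroni(rows: pd.DataFrame, m: int, alpha: float) -> pd.DataFrame:
    """Append Bonferroni-adjusted p-values and significance flags."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    rows = rows.copy()
    rows["p_bonferroni"] = np.minimum(1.0, m * rows["p_raw"])
    rows["significant"] = rows["p_bonferroni"] < alpha
    return rows


# ---------------------------------------------------------------------------
# model / results objects


class GWASResults:
    """Fitted scan results: per-marker table, cofactor report, significance.

    Attributes
    ----------
    scan
        One row per scanned marker, sorted by (chrom, pos), with effect
        estimate, partial R², raw / Bonferroni p, cofactor and significance
        flags.
    cofactor_report
        Selection counts across subsamples plus potential / final flags.
    """

    def __init__(self, model: "MultiLocusGWAS", scan: pd.DataFrame,
                 report: CofactorReport):
        self.model = model
        self.scan = scan.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        self.cofactor_report = report
        self.n = model.data.n
        self.m = model.data.m
        self.alpha = model.config.alpha

    @property
    def significant(self) -> pd.DataFrame:
        return self.scan[self.scan["significant"]].reset_index(drop=True)

    @property
    def cofactors(self) -> pd.DataFrame:
        frame = self.cofactor_report.frame()
        return (
            frame[frame["final_cofactor"]]
            .sort_values("entry_order")
            .reset_index(drop=True)
        )

    def summary(self) -> str:
        lines = [
            "Multi-locus GWAS scan",
            f"  accessions: {self.n}    markers tested: {self.m}",
            f"  final cofactors: {len(self.cofactor_report.final)}",
            f"  significant markers (Bonferroni p < {self.alpha:g}): "
            f"{int(self.scan['significant'].sum())}",
        ]
        sig = self.significant
        if len(sig):
            lines.append("")
            lines.append(
                sig[
                    ["marker_id", "chrom", "pos_bp", "estimate", "partial_r2",
                     "p_raw", "p_bonferroni"]
                ].to_string(index=False)
            )
        return "\n".join(lines)


class MultiLocusGWAS:
    """Association model for one phenotype against a genotype panel.

    Parameters
    ----------
    genotypes
        Major-allele-coded panel.
    phenotype
        Accession-indexed series (trait LS-mean under one treatment, or a
        stress-tolerance index).
    config
        Pipeline constants (seed, subsampling design, alpha, MAF floor).
    prefilter_top
        Within each training subsample, restrict forward selection to this
        many markers by marginal F (``None`` disables the pre-filter).
    max_terms
        Cap on forward-selection model size; default ``min(n // 10, 50)``.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotype: pd.Series,
        config: PipelineConfig | None = None,
        *,
        prefilter_top: int | None = 500,
        max_terms: int | None = None,
    ):
        self.config = config or PipelineConfig()
        self.data = prepare(genotypes, phenotype, self.config)
        self.prefilter_top = prefilter_top
        self.max_terms = max_terms

    def fit(self, rng: np.random.Generator | None = None) -> GWASResults:
        data = self.data
        rng = rng or np.random.default_rng(self.config.seed)
        report = subsample_cofactor_scan(
            data.X, data.y, self.config, rng=rng,
            prefilter_top=self.prefilter_top, max_terms=self.max_terms,
            marker_ids=data.markers["marker_id"],
        )
        report.final = final_cofactors(data.X, data.y, report.potential,
                                       max_terms=self.max_terms)
        scan = snp_scan(data.X, data.y, report.final, data.markers)
        scan = bonferroni(scan, data.m, self.config.alpha)
        return GWASResults(self, scan, report)


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    config: PipelineConfig | None = None,
    **model_kwargs,
) -> dict[str, GWASResults]:
    """Scan every phenotype column (trait x treatment LS-means and indices).

    ``phenotypes`` is accession-indexed with one column per phenotype label.
    Each column gets its own RNG stream derived deterministically from
    ``config.seed`` and the column position, so a fixed seed reproduces every
    scan bit-for-bit regardless of how many labels are run.
    """
    config = config or PipelineConfig()
    labels = list(phenotypes.columns)
    streams = np.random.SeedSequence(config.seed).spawn(len(labels))
    results: dict[str, GWASResults] = {}
    for label, stream in zip(labels, streams):
        model = MultiLocusGWAS(genotypes, phenotypes[label], config, **model_kwargs)
        results[label] = model.fit(rng=np.random.default_rng(stream))
    return results
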
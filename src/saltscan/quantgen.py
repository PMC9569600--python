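"""Quantitative-genetics statistics: ANOVA, heritability, LS-means, correlations.

The experimental design is a completely randomized two-treatment screen with
replicated accessions, analysed with fixed-effects least squares:

* one-way ANOVA per treatment (accession effect vs pooled error),
* combined two-way ANOVA (accession A, treatment T, interaction A x T,
  within-cell error),
* broad-sense heritability from method-of-moments variance components,

      sigma_g^2 = (MS_A - MS_e) / r      (truncated at 0)
      sigma_p^2 = sigma_g^2 + sigma_e^2 / r
      H_b       = 100 * sigma_g^2 / sigma_p^2

  with r the number of replicates,
* coefficient of variation CV% = 100 * sqrt(MS_e) / grand mean,
* least-squares accession means, and
* Pearson correlation matrices with two-sided t-test p-values (pairwise
  deletion, unadjusted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .germination import TRAIT_NAMES

__all__ = [
    "AnovaTable",
    "VarianceComponents",
    "anova_oneway",
    "anova_twoway_combined",
    "cv_percent",
    "r_squared",
    "heritability",
    "ls_means",
    "correlation_matrix",
    "significance_stars",
    "trait_statistics",
]

#: An ANOVA table: DataFrame indexed by source with columns df, ss, ms, F, p.
AnovaTable = pd.DataFrame


@dataclass
class VarianceComponents:
    """Method-of-moments variance components and broad-sense heritability."""

    sigma_g2: float
    sigma_e2: float
    r: float
    truncated: bool  # negative genotypic-variance estimate was clipped to 0

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_e2 / self.r

    @property
    def hb(self) -> float:
        """Broad-sense heritability in percent, in [0, 100]."""
        if self.sigma_p2 == 0:
            return 100.0
        return 100.0 * self.sigma_g2 / self.sigma_p2


def _drop_missing(groups, values):
    groups = np.asarray(groups)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    return groups[keep], values[keep]


def _f_p(f: float, df1: int, df2: int) -> float:
    if df2 <= 0 or not np.isfinite(f):
        return np.nan
    return float(stats.f.sf(f, df1, df2))


def anova_oneway(groups, values) -> AnovaTable:
    """One-way fixed-effects ANOVA of accession effects within one treatment.

    Unbalanced data are handled through per-cell counts:
    SS_A = sum_i n_i (mean_i - grand mean)^2.
    """
    groups, values = _drop_missing(groups, values)
    labels, idx = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("one-way ANOVA needs at least 2 accessions")
    n = len(values)
    counts = np.bincount(idx)
    sums = np.bincount(idx, weights=values)
    cell_means = sums / counts
    grand = values.mean()
    ss_a = float(np.sum(counts * (cell_means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_e = ss_total - ss_a
    df_a = len(labels) - 1
    df_e = n - len(labels)
    ms_a = ss_a / df_a
    ms_e = ss_e / df_e if df_e > 0 else np.nan
    f = ms_a / ms_e if ms_e and np.isfinite(ms_e) and ms_e > 0 else np.inf
    return pd.DataFrame(
        {
            "df": [df_a, df_e],
            "ss": [ss_a, ss_e],
            "ms": [ms_a, ms_e],
            "F": [f, np.nan],
            "p": [_f_p(f, df_a, df_e), np.nan],
        },
        index=pd.Index(["accession", "error"], name="source"),
    )


def anova_twoway_combined(accessions, treatments, values) -> AnovaTable:
    """Combined two-way ANOVA: accession (A), treatment (T), A x T, error.

    The error term is the pooled within-cell residual of the fixed-effects
    completely-randomized layout; main-effect sums of squares use per-level
    counts and the interaction takes the remainder, which in the balanced
    design equals the cell-means decomposition exactly.
    """
    accessions = np.asarray(accessions)
    treatments = np.asarray(treatments)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    accessions, treatments, values = accessions[keep], treatments[keep], values[keep]

    a_labels, a_idx = np.unique(accessions, return_inverse=True)
    t_labels, t_idx = np.unique(treatments, return_inverse=True)
    if len(t_labels) < 2:
        raise ValueError("combined ANOVA needs both treatments present")
    n = len(values)
    grand = values.mean()

    def main_ss(idx, n_levels):
        counts = np.bincount(idx, minlength=n_levels)
        means = np.bincount(idx, weights=values, minlength=n_levels) / counts
        return float(np.sum(counts * (means - grand) ** 2))

    ss_a = main_ss(a_idx, len(a_labels))
    ss_t = main_ss(t_idx, len(t_labels))

    cell_idx = a_idx * len(t_labels) + t_idx
    n_cells_max = len(a_labels) * len(t_labels)
    cell_counts = np.bincount(cell_idx, minlength=n_cells_max)
    occupied = cell_counts > 0
    cell_sums = np.bincount(cell_idx, weights=values, minlength=n_cells_max)
    cell_means = np.where(occupied, cell_sums / np.maximum(cell_counts, 1), 0.0)
    ss_e = float(np.sum((values - cell_means[cell_idx]) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_at = ss_total - ss_a - ss_t - ss_e

    df_a = len(a_labels) - 1
    df_t = len(t_labels) - 1
    df_at = int(occupied.sum()) - 1 - df_a - df_t
    df_e = n - int(occupied.sum())

    dfs = np.array([df_a, df_t, df_at, df_e])
    sss = np.array([ss_a, ss_t, ss_at, ss_e])
    with np.errstate(invalid="ignore", divide="ignore"):
        mss = sss / dfs
    ms_e = mss[-1]
    fs = [ms / ms_e if df_e > 0 and ms_e > 0 else np.inf for ms in mss[:3]] + [np.nan]
    ps = [_f_p(f, d, df_e) for f, d in zip(fs[:3], dfs[:3])] + [np.nan]
    return pd.DataFrame(
        {"df": dfs, "ss": sss, "ms": mss, "F": fs, "p": ps},
        index=pd.Index(["accession", "treatment", "interaction", "error"], name="source"),
    )


def r_squared(anova: AnovaTable) -> float:
    """Model R^2 = 1 - SS_error / SS_total from an ANOVA table."""
    ss_total = float(anova["ss"].sum())
    if ss_total == 0:
        return np.nan
    return 1.0 - float(anova.loc["error", "ss"]) / ss_total


def cv_percent(ms_error: float, grand_mean: float) -> float:
    """CV% = 100 * sqrt(MS_error) / grand mean."""
    if grand_mean == 0:
        raise ValueError("grand mean is zero; CV%% undefined")
    return 100.0 * np.sqrt(ms_error) / abs(grand_mean)


def heritability(ms_accession: float, ms_error: float, r: float) -> VarianceComponents:
    """Variance components and H_b from accession and error mean squares."""
    if r < 1:
        raise ValueError("replicate count r must be >= 1")
    raw = (ms_accession - ms_error) / r
    return VarianceComponents(
        sigma_g2=max(0.0, raw), sigma_e2=ms_error, r=float(r), truncated=raw < 0
    )


def ls_means(groups, values) -> pd.Series:
    """Least-squares accession means from the one-way fixed-effects model.

    Solved through the normal equations of the dummy-coded design; for the
    one-way layout this reproduces the per-accession arithmetic cell means,
    balanced or not.
    """
    groups, values = _drop_missing(groups, values)
    labels, idx = np.unique(groups, return_inverse=True)
    # cell-mean parameterisation: X is an orthogonal indicator design
    x = np.zeros((len(values), len(labels)))
    x[np.arange(len(values)), idx] = 1.0
    coef, *_ = np.linalg.lstsq(x, values, rcond=None)
    return pd.Series(coef, index=labels, name="ls_mean")


def significance_stars(p: float) -> str:
    """Presentation stars at the 0.1 / 0.05 / 0.01 / 0.001 levels."""
    if not np.isfinite(p):
        return ""
    for threshold, symbol in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, ".")):
        if p < threshold:
            return symbol
    return ""


def correlation_matrix(table: pd.DataFrame, columns: list[str] | None = None):
    """Pairwise-deletion Pearson correlations with two-sided t-test p-values.

    Returns ``(r, p, stars)`` DataFrames. Pairs involving a zero-variance
    column, or with fewer than 3 complete observations, are missing.
    """
    columns = columns or [c for c in TRAIT_NAMES if c in table.columns]
    k = len(columns)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    data = table[columns].to_numpy(dtype=float)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            pair = data[:, [i, j]]
            pair = pair[np.isfinite(pair).all(axis=1)]
            if len(pair) < 3 or pair[:, 0].std() == 0 or pair[:, 1].std() == 0:
                continue
            res = stats.pearsonr(pair[:, 0], pair[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=columns, columns=columns)
    p_df = pd.DataFrame(p, index=columns, columns=columns)
    stars = p_df.map(significance_stars)
    return r_df, p_df, stars


def trait_statistics(trait_table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait summary: separate ANOVA per treatment plus combined ANOVA.

    One row per trait with, for each treatment, the accession mean square,
    CV%, model R^2 and broad-sense heritability, and the combined-ANOVA mean
    squares for treatment, accession and interaction with their p-values.
    """
    traits = traits or [t for t in TRAIT_NAMES if t in trait_table.columns]
    rows = []
    for trait in traits:
        row: dict[str, float | str] = {"trait": trait}
        for treatment in ("control", "salinity"):
            sub = trait_table[trait_table["treatment"] == treatment]
            values = sub[trait].to_numpy(dtype=float)
            finite = np.isfinite(values)
            anova = anova_oneway(sub["accession"].to_numpy()[finite], values[finite])
            r = finite.sum() / sub["accession"].nunique()
            vc = heritability(anova.loc["accession", "ms"], anova.loc["error", "ms"], r)
            prefix = "control" if treatment == "control" else "salinity"
            row[f"{prefix}_ms_accession"] = anova.loc["accession", "ms"]
            row[f"{prefix}_p_accession"] = anova.loc["accession", "p"]
            row[f"{prefix}_cv_pct"] = cv_percent(
                anova.loc["error", "ms"], values[finite].mean()
            )
            row[f"{prefix}_r2"] = r_squared(anova)
            row[f"{prefix}_hb"] = vc.hb
        finite = trait_table[trait].notna()
        combined = anova_twoway_combined(
            trait_table.loc[finite, "accession"],
            trait_table.loc[finite, "treatment"],
            trait_table.loc[finite, trait],
        )
        row["combined_ms_treatment"] = combined.loc["treatment", "ms"]
        row["combined_ms_accession"] = combined.loc["accession", "ms"]
        row["combined_ms_interaction"] = combined.loc["interaction", "ms"]
        row["combined_p_treatment"] = combined.loc["treatment", "p"]
        row["combined_p_accession"] = combined.loc["accession", "p"]
        row["combined_p_interaction"] = combined.loc["interaction", "p"]
        rows.append(row)
    return pd.DataFrame(rows)
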
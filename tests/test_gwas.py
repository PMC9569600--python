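"""Multi-locus scan machinery: preparation, selection, sequential tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saltscan.config import PipelineConfig
from saltscan.genotypes import GenotypeMatrix
from saltscan.gwas import (
    MultiLocusGWAS,
    bonferroni,
    final_cofactors,
    forward_select_sbc,
    prepare,
    snp_scan,
    subsample_cofactor_scan,
)


def make_gm(calls, accessions=None):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chrom": ["1H"] * m,
            "pos_bp": np.arange(1, m + 1) * 1000,
        }
    )
    return GenotypeMatrix(accessions or [f"a{i}" for i in range(n)], markers, calls)


class TestPrepare:
    def test_monomorphic_and_low_maf_removed(self, rng):
        calls = rng.binomial(1, 0.5, (30, 4)).astype(float)
        calls[:, 1] = 1.0  # monomorphic
        calls[:, 2] = 1.0
        calls[0, 2] = 0.0  # maf 1/30 < 0.1
        gm = make_gm(calls)
        ph = pd.Series(rng.normal(0, 1, 30), index=gm.accessions)
        data = prepare(gm, ph, PipelineConfig(maf_min=0.1))
        assert data.m == 2
        assert data.n_removed_monomorphic == 1
        assert data.n_removed_maf == 1

    def test_maf_floor_zero_keeps_polymorphic(self, rng):
        calls = rng.binomial(1, 0.5, (30, 4)).astype(float)
        calls[5, 0] = np.nan
        gm = make_gm(calls)
        ph = pd.Series(rng.normal(0, 1, 30), index=gm.accessions)
        data = prepare(gm, ph, PipelineConfig(maf_min=0.0))
        assert data.m == 4

    def test_missing_imputed_to_allele_frequency(self):
        calls = np.ones((24, 1))
        calls[:6, 0] = 0.0
        calls[0, 0] = np.nan  # observed frequency 18/23
        gm = make_gm(calls)
        ph = pd.Series(np.arange(24.0), index=gm.accessions)
        data = prepare(gm, ph)
        assert data.X[0, 0] == pytest.approx(18 / 23)

    def test_too_few_shared_accessions_rejected(self, rng):
        gm = make_gm(rng.binomial(1, 0.5, (30, 3)))
        ph = pd.Series(rng.normal(0, 1, 10), index=gm.accessions[:10])
        with pytest.raises(ValueError, match="20"):
            prepare(gm, ph)


def exhaustive_sbc(X, y, max_size):
    """Global SBC minimum over all subsets up to max_size (brute force)."""
    n, m = X.shape
    best = (np.inf, ())
    for size in range(0, max_size + 1):
        for subset in itertools.combinations(range(m), size):
            d = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
            if np.linalg.matrix_rank(d) < d.shape[1]:
                continue
            r = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
            rss = float(r @ r)
            sbc = -np.inf if rss <= 0 else n * np.log(rss / n) + (size + 1) * np.log(n)
            if sbc < best[0]:
                best = (sbc, subset)
    return best


class TestForwardSelection:
    def test_exact_signal_recovered_alone(self, rng):
        X = rng.binomial(1, 0.4, (40, 12)).astype(float)
        selected, _ = forward_select_sbc(X, X[:, 5].copy())
        assert selected == [5]

    def test_null_selection_rate_bounded(self):
        """Under a global null the empty model should be kept most of the time.

        With 50 independent candidates at n = 200, the chance that the best
        single-marker SBC beats the intercept is roughly the chance that the
        max of 50 chi-square(1) draws exceeds n*ln(1+F/(n-2)) ~ ln n; the
        closed-form bound gives a selection rate near 1 - (1-p*)^50 with
        p* = P(F_{1,198} > threshold). The observed rate must stay within
        binomial error of that bound.
        """
        n, m, seeds = 200, 50, 40
        thresh = (np.exp(np.log(n) / n) - 1) * (n - 2)
        p_star = stats.f.sf(thresh, 1, n - 2)
        expected = 1 - (1 - p_star) ** m  # upper bound: candidates ~independent
        hits = 0
        for s in range(seeds):
            rng = np.random.default_rng(s)
            X = rng.binomial(1, 0.5, (n, m)).astype(float)
            y = rng.normal(0, 1, n)
            selected, _ = forward_select_sbc(X, y)
            hits += bool(selected)
        rate = hits / seeds
        margin = 3 * np.sqrt(expected * (1 - expected) / seeds)
        assert rate <= expected + margin

    def test_matches_exhaustive_search_nested_truth(self, rng):
        X = rng.binomial(1, 0.5, (60, 7)).astype(float)
        y = 1.5 * X[:, 1] + 1.0 * X[:, 4] + rng.normal(0, 0.3, 60)
        selected, sbc_path = forward_select_sbc(X, y)
        best_sbc, best_subset = exhaustive_sbc(X, y, max_size=4)
        assert set(selected) == set(best_subset)
        assert sbc_path[-1] == pytest.approx(best_sbc, abs=1e-9)

    def test_sbc_path_decreasing(self, rng):
        X = rng.binomial(1, 0.5, (60, 10)).astype(float)
        y = X[:, 0] + rng.normal(0, 0.5, 60)
        _, sbc_path = forward_select_sbc(X, y)
        assert (np.diff(sbc_path) < 0).all()


class TestSubsampleScan:
    def test_strong_qtl_selected_often(self, rng):
        n = 192
        X = rng.binomial(1, 0.5, (n, 100)).astype(float)
        y = X[:, 30] + rng.normal(0, 1, n)  # ~ h2 0.2 single QTL
        config = PipelineConfig(seed=1)
        report = subsample_cofactor_scan(X, y, config, rng=np.random.default_rng(1))
        assert report.counts[30] >= 50
        assert 30 in report.potential

    def test_zero_subsamples_empty_report(self, rng):
        X = rng.binomial(1, 0.5, (40, 10)).astype(float)
        report = subsample_cofactor_scan(
            X, rng.normal(0, 1, 40), PipelineConfig(seed=1, n_subsamples=0)
        )
        assert report.counts.sum() == 0
        assert len(report.potential) == 0


class TestFinalCofactors:
    def test_empty_potential_set(self, rng):
        X = rng.binomial(1, 0.5, (40, 10)).astype(float)
        assert final_cofactors(X, rng.normal(0, 1, 40), np.array([], dtype=int)) == []

    def test_perfect_ld_copy_collapses_to_one(self, rng):
        X = rng.binomial(1, 0.5, (60, 5)).astype(float)
        X[:, 3] = X[:, 1]
        y = X[:, 1] + rng.normal(0, 0.4, 60)
        selected = final_cofactors(X, y, np.array([1, 3]))
        assert len(selected) == 1 and selected[0] in (1, 3)

    def test_subset_of_potential(self, rng):
        X = rng.binomial(1, 0.5, (60, 20)).astype(float)
        y = X[:, 2] - X[:, 9] + rng.normal(0, 0.5, 60)
        potential = np.array([2, 5, 9, 11])
        assert set(final_cofactors(X, y, potential)) <= set(potential)


class TestSnpScan:
    def test_no_cofactors_matches_marginal_regression(self, rng):
        X = rng.binomial(1, 0.4, (50, 10)).astype(float)
        y = X[:, 3] * 0.8 + rng.normal(0, 1, 50)
        rows = snp_scan(X, y, [])
        for j in range(10):
            oracle = stats.linregress(X[:, j], y)
            assert rows.loc[j, "p_raw"] == pytest.approx(oracle.pvalue, abs=1e-10)
            assert rows.loc[j, "estimate"] == pytest.approx(oracle.slope, abs=1e-10)

    def test_sequential_f_matches_rss_oracle(self, rng):
        n = 60
        X = rng.binomial(1, 0.4, (n, 8)).astype(float)
        y = X[:, 2] * 0.9 + rng.normal(0, 1, n)
        cof = [2, 5]

        def rss(cols):
            d = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
            r = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
            return float(r @ r)

        rows = snp_scan(X, y, cof)
        for j in range(8):
            if j in cof:
                continue
            r0, r1 = rss(cof), rss(cof + [j])
            df2 = n - len(cof) - 2
            p = stats.f.sf((r0 - r1) / (r1 / df2), 1, df2)
            assert rows.loc[j, "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_cofactor_tested_at_entry_position(self, rng):
        """A cofactor's own p is its sequential test given its predecessors."""
        n = 60
        X = rng.binomial(1, 0.4, (n, 8)).astype(float)
        y = X[:, 2] * 0.9 + X[:, 5] * 0.5 + rng.normal(0, 1, n)
        rows = snp_scan(X, y, [2, 5])
        # first cofactor: marginal test
        oracle = stats.linregress(X[:, 2], y)
        assert rows.loc[2, "p_raw"] == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_orthogonal_marker_null_calibration(self):
        n = 100
        ps = []
        for s in range(200):
            rng = np.random.default_rng(s)
            x = rng.binomial(1, 0.5, (n, 1)).astype(float)
            y = rng.normal(0, 1, n)
            ps.append(snp_scan(x, y, []).loc[0, "p_raw"])
        # raw p uniform under the null: KS test should not reject
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_perfect_fit_partial_r2_100(self, rng):
        X = rng.binomial(1, 0.5, (30, 4)).astype(float)
        rows = snp_scan(X, X[:, 1].copy(), [])
        assert rows.loc[1, "partial_r2"] == pytest.approx(100.0)
        assert rows.loc[1, "p_raw"] <= 1e-200

    def test_major_allele_sign_convention(self, rng):
        x = rng.binomial(1, 0.7, 80).astype(float)  # 1 = major allele
        y = 2.0 * x + rng.normal(0, 0.5, 80)
        rows = snp_scan(x[:, None], y, [])
        assert rows.loc[0, "estimate"] > 0


class TestBonferroni:
    def test_screening_scale_arithmetic(self):
        rows = pd.DataFrame({"p_raw": [4.0e-6, 0.5]})
        out = bonferroni(rows, 10323, alpha=0.05)
        assert out.loc[0, "p_bonferroni"] == pytest.approx(0.0413, abs=1e-4)
        assert bool(out.loc[0, "significant"])
        assert out.loc[1, "p_bonferroni"] == 1.0

    def test_monotone_in_m(self, rng):
        rows = pd.DataFrame({"p_raw": rng.uniform(0, 1, 50)})
        sig_small = bonferroni(rows, 100, 0.05)["significant"]
        sig_large = bonferroni(rows, 10000, 0.05)["significant"]
        assert not (sig_large & ~sig_small).any()


class TestModelFit:
    def test_seed_reproducibility(self, tiny_panel):
        ph = pd.Series(
            np.random.default_rng(0).normal(0, 1, tiny_panel.genotypes.n_accessions),
            index=tiny_panel.genotypes.accessions,
        )
        config = PipelineConfig(seed=4, n_subsamples=20)
        a = MultiLocusGWAS(tiny_panel.genotypes, ph, config).fit()
        b = MultiLocusGWAS(tiny_panel.genotypes, ph, config).fit()
        pd.testing.assert_frame_equal(a.scan, b.scan)
        np.testing.assert_array_equal(
            a.cofactor_report.counts, b.cofactor_report.counts
        )

    def test_scan_sorted_and_summary_runs(self, tiny_panel):
        ph = pd.Series(
            np.random.default_rng(1).normal(0, 1, tiny_panel.genotypes.n_accessions),
            index=tiny_panel.genotypes.accessions,
        )
        res = MultiLocusGWAS(
            tiny_panel.genotypes, ph, PipelineConfig(seed=4, n_subsamples=10)
        ).fit()
        scan = res.scan
        assert scan.equals(
            scan.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        )
        assert "Multi-locus GWAS" in res.summary()
        assert res.cofactor_report.frame()["final_cofactor"].sum() == len(
            res.cofactor_report.final
        )
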
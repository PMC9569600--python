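"""ANOVA, heritability, LS-means and correlations against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from saltscan.quantgen import (
    anova_oneway,
    anova_twoway_combined,
    correlation_matrix,
    cv_percent,
    heritability,
    ls_means,
    r_squared,
    significance_stars,
)


def statsmodels_oneway(groups, values):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"g": groups, "y": values})
    model = ols("y ~ C(g)", data=df).fit()
    return sm.stats.anova_lm(model, typ=1)


class TestOneWay:
    def test_hand_sums_of_squares(self):
        # accessions {1,1} and {3,3}: between-MS 4, error-MS 0
        table = anova_oneway(["a", "a", "b", "b"], [1.0, 1.0, 3.0, 3.0])
        assert table.loc["accession", "ms"] == pytest.approx(4.0)
        assert table.loc["error", "ms"] == pytest.approx(0.0)

    def test_constant_data(self):
        table = anova_oneway(["a", "a", "b", "b"], [2.0] * 4)
        assert table.loc["accession", "ms"] == 0.0

    def test_single_accession_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway(["a", "a"], [1.0, 2.0])

    def test_matches_regression_decomposition(self, rng):
        groups = np.repeat([f"a{i}" for i in range(50)], 3)
        values = rng.normal(0, 1, 150) + np.repeat(rng.normal(0, 1, 50), 3)
        ours = anova_oneway(groups, values)
        oracle = statsmodels_oneway(groups, values)
        assert ours.loc["accession", "ss"] == pytest.approx(
            oracle.loc["C(g)", "sum_sq"], abs=1e-8
        )
        assert ours.loc["error", "ss"] == pytest.approx(
            oracle.loc["Residual", "sum_sq"], abs=1e-8
        )
        assert ours.loc["accession", "p"] == pytest.approx(
            oracle.loc["C(g)", "PR(>F)"], abs=1e-10
        )

    def test_unbalanced_per_cell_counts(self, rng):
        groups = ["a"] * 2 + ["b"] * 5 + ["c"] * 3
        values = rng.normal(0, 1, 10)
        ours = anova_oneway(groups, values)
        oracle = statsmodels_oneway(groups, values)
        assert ours.loc["accession", "ss"] == pytest.approx(
            oracle.loc["C(g)", "sum_sq"], abs=1e-8
        )


class TestTwoWayCombined:
    def test_degrees_of_freedom_full_panel(self, rng):
        a = 208
        accessions = np.repeat([f"A{i}" for i in range(a)], 6)
        treatments = np.tile(np.repeat(["control", "salinity"], 3), a)
        values = rng.normal(0, 1, a * 6)
        table = anova_twoway_combined(accessions, treatments, values)
        assert table.loc["accession", "df"] == 207
        assert table.loc["treatment", "df"] == 1
        assert table.loc["interaction", "df"] == 207
        assert table["df"].sum() == a * 6 - 1

    def test_additive_truth_no_interaction(self):
        accessions = np.repeat(["a", "b", "c"], 4)
        treatments = np.tile(np.repeat(["control", "salinity"], 2), 3)
        effect = {"a": 0.0, "b": 1.0, "c": 2.0}
        values = np.array(
            [effect[g] + (0.5 if t == "salinity" else 0.0)
             for g, t in zip(accessions, treatments)]
        )
        table = anova_twoway_combined(accessions, treatments, values)
        assert table.loc["interaction", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["error", "ss"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_cell_means(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        accessions = np.repeat([f"A{i}" for i in range(5)], 6)
        treatments = np.tile(np.repeat(["control", "salinity"], 3), 5)
        values = rng.normal(0, 1, 30)
        ours = anova_twoway_combined(accessions, treatments, values)
        df = pd.DataFrame({"a": accessions, "t": treatments, "y": values})
        oracle = sm.stats.anova_lm(ols("y ~ C(a) * C(t)", data=df).fit(), typ=1)
        assert ours.loc["accession", "ss"] == pytest.approx(
            oracle.loc["C(a)", "sum_sq"], abs=1e-8
        )
        assert ours.loc["treatment", "ss"] == pytest.approx(
            oracle.loc["C(t)", "sum_sq"], abs=1e-8
        )
        assert ours.loc["interaction", "ss"] == pytest.approx(
            oracle.loc["C(a):C(t)", "sum_sq"], abs=1e-8
        )
        assert ours.loc["error", "ss"] == pytest.approx(
            oracle.loc["Residual", "sum_sq"], abs=1e-8
        )

    def test_missing_treatment_rejected(self):
        with pytest.raises(ValueError):
            anova_twoway_combined(["a", "b"], ["control", "control"], [1.0, 2.0])


class TestCvAndR2:
    def test_examples(self):
        assert cv_percent(0.0, 5.0) == 0.0
        assert cv_percent(4.0, 20.0) == pytest.approx(10.0)

    def test_scale_invariance(self, rng):
        groups = np.repeat(["a", "b", "c"], 3)
        values = rng.uniform(5, 10, 9)
        for c in (1.0, 3.7):
            table = anova_oneway(groups, c * values)
            cv = cv_percent(table.loc["error", "ms"], (c * values).mean())
            if c == 1.0:
                base = cv
        assert cv == pytest.approx(base)

    def test_r2_bounds_and_perfect_fit(self, rng):
        groups = np.repeat(["a", "b", "c"], 3)
        noisy = anova_oneway(groups, rng.normal(0, 1, 9))
        assert 0.0 <= r_squared(noisy) <= 1.0
        perfect = anova_oneway(groups, np.repeat([1.0, 2.0, 3.0], 3))
        assert r_squared(perfect) == pytest.approx(1.0)


class TestHeritability:
    def test_hand_arithmetic(self):
        vc = heritability(10.0, 1.0, 3)
        assert vc.sigma_g2 == pytest.approx(3.0)
        assert vc.sigma_p2 == pytest.approx(3.0 + 1.0 / 3.0)
        assert vc.hb == pytest.approx(90.0)

    def test_boundaries(self):
        assert heritability(5.0, 5.0, 3).hb == 0.0
        assert heritability(5.0, 0.0, 3).hb == 100.0

    def test_negative_component_truncated(self):
        vc = heritability(1.0, 5.0, 3)
        assert vc.sigma_g2 == 0.0 and vc.truncated and vc.hb == 0.0

    def test_monotone_in_accession_ms(self):
        hbs = [heritability(ms, 2.0, 3).hb for ms in (2.0, 4.0, 8.0, 16.0)]
        assert hbs == sorted(hbs)


class TestLsMeans:
    def test_balanced_and_single(self):
        means = ls_means(["a", "a", "a", "b"], [1.0, 2.0, 3.0, 7.0])
        assert means["a"] == pytest.approx(2.0)
        assert means["b"] == pytest.approx(7.0)

    def test_unbalanced_matches_normal_equations(self, rng):
        groups = np.array(["a"] * 5 + ["b"] * 2 + ["c"] * 3)
        values = rng.normal(0, 1, 10)
        ours = ls_means(groups, values)
        labels, idx = np.unique(groups, return_inverse=True)
        x = np.zeros((10, 3))
        x[np.arange(10), idx] = 1
        oracle = np.linalg.solve(x.T @ x, x.T @ values)
        np.testing.assert_allclose(ours[labels].to_numpy(), oracle, atol=1e-10)


class TestCorrelation:
    def test_self_and_antithetic(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        table["y"] = -table["x"]
        r, p, _ = correlation_matrix(table, ["x", "y"])
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_textbook_formula_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 7.0])
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, _, _ = correlation_matrix(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(expected)

    def test_zero_variance_missing(self):
        table = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        r, _, _ = correlation_matrix(table, ["x", "y"])
        assert np.isnan(r.loc["x", "y"])

    def test_stars(self):
        assert significance_stars(5e-4) == "***"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.5) == ""
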
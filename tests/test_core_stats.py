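"""Residualization and the per-SNP statistics S and T."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nullsnp import (
    ComputationError,
    ValidationError,
    fit_covariate_residuals,
    genotype_residuals,
    regression_ss,
    statistic_S,
    statistic_T,
)


class TestCovariateResiduals:
    @pytest.mark.parametrize(
        "values, covariates, expected",
        [
            ([1, 2, 3], None, [-1, 0, 1]),  # intercept-only fit is centering
            ([0.5, 1.5, 2.5], [[0.5], [1.5], [2.5]], [0, 0, 0]),  # perfect fit
            ([2, 1, 4, 3], [[0], [0], [1], [1]], [0.5, -0.5, 0.5, -0.5]),  # group-mean subtraction
        ],
    )
    def test_ols_residual_examples(self, values, covariates, expected):
        rv = fit_covariate_residuals(values, covariates)
        np.testing.assert_allclose(rv.values, expected, atol=1e-12)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(0)
        cov = rng.standard_normal((40, 3))
        rv = fit_covariate_residuals(rng.standard_normal(40), cov)
        assert abs(rv.values.mean()) < 1e-10
        for j in range(3):
            assert abs(rv.values @ cov[:, j]) < 1e-6 * np.linalg.norm(rv.values) * np.linalg.norm(cov[:, j])

    def test_rank_deficient_design_names_columns(self):
        x = np.arange(6, dtype=float)
        # pivoted QR may blame either member of the collinear pair
        with pytest.raises(ValidationError, match="Age|Dup"):
            fit_covariate_residuals(
                np.ones(6), np.column_stack([x, 2 * x]), covariate_names=["Age", "Dup"]
            )

    def test_too_few_individuals(self):
        with pytest.raises(ValidationError):
            fit_covariate_residuals([1.0, 2.0], np.ones((2, 3)))

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_covariate_residuals([1.0, np.nan, 2.0])


class TestGenotypeResiduals:
    def test_fits_on_nonmissing_subset(self):
        gr = genotype_residuals([0, 1, 2, np.nan])
        np.testing.assert_allclose(gr.residuals.values, [-1, 0, 1], atol=1e-12)
        np.testing.assert_array_equal(gr.residuals.index, [0, 1, 2])
        assert gr.n_star == 3
        assert not gr.monomorphic

    def test_monomorphic_flagged_not_error(self):
        gr = genotype_residuals([2.0, 2.0, 2.0, 2.0])
        assert gr.monomorphic
        np.testing.assert_array_equal(gr.residuals.values, 0.0)

    def test_genotype_fully_explained_by_covariate(self):
        gr = genotype_residuals([0, 0, 1, 1], [[0], [0], [1], [1]])
        np.testing.assert_allclose(gr.residuals.values, 0.0, atol=1e-12)

    def test_too_few_nonmissing_is_unanalyzable(self):
        with pytest.raises(ComputationError, match="unanalyzable"):
            genotype_residuals([0, 1, np.nan, np.nan], [[1], [2], [3], [4]])


class TestStatisticS:
    @pytest.mark.parametrize(
        "g_star, y_star, expected",
        [
            ([0, 0, 0], [1, -2, 1], 0.0),
            ([1, -1], [1, -1], 2.0),
            ([1, 0, -1], [-1, 0, 1], 4.0 / 3.0),  # sign of cross-product irrelevant
        ],
    )
    def test_direct_arithmetic(self, g_star, y_star, expected):
        from nullsnp.core_stats import ResidualVector

        idx = np.arange(len(g_star))
        g = ResidualVector(values=g_star, source="genotype", index=idx)
        y = ResidualVector(values=y_star, source="phenotype", index=idx)
        assert statistic_S(g, y, len(idx)) == pytest.approx(expected, abs=1e-12)

    def test_index_mismatch_rejected(self):
        from nullsnp.core_stats import ResidualVector

        g = ResidualVector(values=[1.0, -1.0], source="genotype", index=[0, 1])
        y = ResidualVector(values=[1.0, -1.0], source="phenotype", index=[0, 2])
        with pytest.raises(ValidationError):
            statistic_S(g, y, 2)

    def test_absolute_form_is_sqrt_of_squared_times_scale(self):
        from nullsnp.core_stats import ResidualVector

        idx = np.arange(4)
        g = ResidualVector(values=[1.5, -0.5, -0.5, -0.5], source="genotype", index=idx)
        y = ResidualVector(values=[2.0, -1.0, 0.0, -1.0], source="phenotype", index=idx)
        s_sq = statistic_S(g, y, 4, form="squared")
        s_abs = statistic_S(g, y, 4, form="absolute")
        assert s_sq == pytest.approx(s_abs**2 * 4)

    @given(
        y=arrays(float, 8, elements=st.floats(-5, 5)),
        g=arrays(float, 8, elements=st.sampled_from([0.0, 1.0, 2.0])),
        c=st.floats(0.1, 10),
    )
    def test_coding_symmetry_and_scale(self, y, g, c):
        """Swapping the counted allele (g -> 2-g) leaves S unchanged; scaling
        y* by c multiplies S by c^2."""
        from nullsnp.core_stats import ResidualVector

        idx = np.arange(8)
        y_star = fit_covariate_residuals(y, index=idx)
        g_a = fit_covariate_residuals(g, source="genotype", index=idx)
        g_b = fit_covariate_residuals(2.0 - g, source="genotype", index=idx)
        s_a = statistic_S(g_a, y_star, 8)
        s_b = statistic_S(g_b, y_star, 8)
        assert s_a == pytest.approx(s_b, rel=1e-9, abs=1e-12)
        y_scaled = ResidualVector(values=c * y_star.values, source="phenotype", index=idx)
        assert statistic_S(g_a, y_scaled, 8) == pytest.approx(c * c * s_a, rel=1e-9, abs=1e-12)


class TestStatisticT:
    def test_orthogonal_genotype_gives_null_t(self):
        t = statistic_T([0, 1, 0, 1], [1, 1, -1, -1])
        assert t.t_value == pytest.approx(0.0, abs=1e-12)
        assert t.t_pvalue == pytest.approx(1.0)

    def test_matches_statsmodels_ols(self):
        """Independent oracle: full-design OLS fit via statsmodels, with
        missing genotypes and one covariate."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        n = 50
        cov = rng.standard_normal((n, 1))
        g = rng.binomial(2, 0.3, n).astype(float)
        g[rng.choice(n, 5, replace=False)] = np.nan
        y = 0.4 * cov[:, 0] + 0.3 * np.nan_to_num(g) + rng.standard_normal(n)
        res = statistic_T(g, y, cov)
        obs = ~np.isnan(g)
        X = sm.add_constant(np.column_stack([cov[obs], g[obs]]))
        fit = sm.OLS(y[obs], X).fit()
        assert res.t_value == pytest.approx(fit.tvalues[-1], abs=1e-8)
        assert res.t_pvalue == pytest.approx(fit.pvalues[-1], abs=1e-8)
        assert res.n_star == int(obs.sum())

    def test_allele_coding_flips_sign_only(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.4, 30).astype(float)
        y = 0.5 * g + rng.standard_normal(30)
        a = statistic_T(g, y)
        b = statistic_T(2.0 - g, y)
        assert a.t_value == pytest.approx(-b.t_value, rel=1e-9)
        assert a.t_pvalue == pytest.approx(b.t_pvalue, rel=1e-9)

    def test_monomorphic_returns_sentinel(self):
        res = statistic_T(np.zeros(10), np.arange(10.0))
        assert np.isnan(res.t_value) and np.isnan(res.t_pvalue)

    def test_collinear_genotype_returns_sentinel(self):
        cov = np.array([[0.0], [0.0], [1.0], [1.0], [0.0], [1.0]])
        res = statistic_T(cov[:, 0] * 2, np.arange(6.0), cov)
        assert np.isnan(res.t_value)

    def test_t_df_override_changes_reference_only(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, 40).astype(float)
        y = 0.3 * g + rng.standard_normal(40)
        std = statistic_T(g, y)
        cauchy = statistic_T(g, y, t_df=1)
        assert cauchy.t_value == std.t_value
        assert cauchy.t_pvalue > std.t_pvalue  # t(1) has far heavier tails


class TestRegressionSS:
    def test_orthogonal_vectors_give_zero(self):
        assert regression_ss([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_regression_returns_total_ss(self):
        y = np.array([0.0, 1, 2, 5])
        yc = y - y.mean()
        assert regression_ss(y, y) == pytest.approx(yc @ yc)

    def test_equals_anova_decomposition(self):
        """Oracle: SS_total - SS_residual of the simple linear fit."""
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.3, 80).astype(float)
        y = 0.5 * g + rng.standard_normal(80)
        # genotype is the response in this regression: decompose the g ~ y fit
        slope, intercept = np.polyfit(y, g, 1)
        resid = g - (intercept + slope * y)
        ss_total = float(((g - g.mean()) ** 2).sum())
        assert regression_ss(g, y) == pytest.approx(ss_total - float(resid @ resid), abs=1e-8)

    def test_constant_trait_rejected(self):
        with pytest.raises(ComputationError):
            regression_ss([0, 1, 2], [3.0, 3.0, 3.0])


@given(
    g=arrays(float, 20, elements=st.sampled_from([0.0, 1.0, 2.0])),
    y=arrays(float, 20, elements=st.sampled_from([0.0, 1.0])),
)
def test_binary_trait_cross_product_identity(g, y):
    """With a 0/1 trait the centered cross-product equals (n1 n0 / n)(gbar1 - gbar0),
    i.e. it is proportional to the counted-allele frequency difference between
    the two phenotype groups."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    cross = float((g - g.mean()) @ (y - y.mean()))
    if n1 == 0 or n0 == 0:
        assert cross == pytest.approx(0.0, abs=1e-10)
        return
    gbar1 = g[y == 1].mean()
    gbar0 = g[y == 0].mean()
    assert cross == pytest.approx(n1 * n0 / len(y) * (gbar1 - gbar0), abs=1e-10)
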
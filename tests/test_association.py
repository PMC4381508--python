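"""Unit tests for the four association tests on female genotype/phenotype vectors."""

import math

import numpy as np
import pytest
from scipy import stats

from xvartest import (
    FemaleSample,
    combined_test,
    median_deviations,
    standard_association_test,
    stouffer_combine,
    variance_test,
    weighted_association_test,
)


def sample(g, y):
    return FemaleSample(np.asarray(g), np.asarray(y, dtype=float))


# Fixed 8-observation dataset: het {0,2,6,8}, hom0 {0,2}, hom2 {0,4}.
HAND_SAMPLE = sample([1, 1, 1, 1, 0, 0, 2, 2], [0, 2, 6, 8, 0, 2, 0, 4])


class TestFemaleSample:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            sample([], [])
        with pytest.raises(ValueError):
            sample([0, 3], [1.0, 2.0])
        with pytest.raises(ValueError):
            sample([0, 1], [1.0])
        with pytest.raises(ValueError):
            sample([0, 1], [1.0, np.nan])


class TestMedianDeviations:
    def test_het_group_deviations(self):
        z, _ = median_deviations(sample([1, 1, 1, 1], [0, 2, 6, 8]))
        np.testing.assert_allclose(z, [4, 2, 2, 4])

    def test_constant_group_gives_zero(self):
        z, _ = median_deviations(sample([1, 1, 1], [5, 5, 5]))
        np.testing.assert_allclose(z, [0, 0, 0])

    def test_homozygotes_centered_per_group_before_pooling(self):
        # g0 = {0, 2} (median 1), g2 = {0, 4} (median 2): pooled z = {1,1,2,2}
        s = sample([0, 0, 2, 2, 1, 1], [0, 2, 0, 4, 1, 2])
        z, summary = median_deviations(s)
        np.testing.assert_allclose(z[:4], [1, 1, 2, 2])
        assert summary.mean_z_hom == pytest.approx(1.5)
        assert (summary.n0, summary.n1, summary.n2) == (2, 2, 2)

    def test_group_variances_use_n_minus_1(self):
        _, summary = median_deviations(HAND_SAMPLE)
        assert summary.group_variances[1] == pytest.approx(
            np.var([0, 2, 6, 8], ddof=1)
        )


class TestVarianceTest:
    def test_hand_computed_statistic_and_df(self):
        res = variance_test(HAND_SAMPLE)
        assert res.valid
        assert res.statistic == pytest.approx(1.5 / math.sqrt(5 / 12), rel=1e-12)
        assert res.statistic == pytest.approx(2.3238, abs=5e-5)
        assert res.df == pytest.approx(75 / 17, rel=1e-12)  # ~4.412
        assert res.p_value == pytest.approx(
            float(stats.t.sf(res.statistic, res.df))
        )
        assert res.direction == 1

    def test_two_sided_doubles_upper_tail(self):
        one = variance_test(HAND_SAMPLE)
        two = variance_test(HAND_SAMPLE, two_sided=True)
        assert two.p_value == pytest.approx(2 * one.p_value)

    def test_identical_dispersion_gives_zero_statistic(self):
        s = sample([1, 1, 1, 1, 0, 0, 2, 2], [-1, 1, -2, 2, -1, 1, -2, 2])
        res = variance_test(s)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5)
        assert res.direction == 0

    def test_degenerate_groups_are_invalid_not_raised(self):
        assert not variance_test(sample([1, 0, 0, 2], [1, 2, 3, 4])).valid
        # constant phenotypes: both z-variances zero
        assert not variance_test(sample([1, 1, 0, 0], [3, 3, 3, 3])).valid


class TestWeightedTest:
    def test_equal_group_means_give_zero_slope(self):
        res = weighted_association_test(
            sample([0, 0, 1, 1, 2, 2], [1, -1, 2, -2, 1, -1])
        )
        assert res.valid
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        # 9 points, 3 per group, unequal group variances
        g = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        y = np.array([1.0, 2.0, 3.0, 2.0, 6.0, 10.0, 3.5, 4.0, 4.5])
        w = np.empty(9)
        for code in (0, 1, 2):
            w[g == code] = 1.0 / np.var(y[g == code], ddof=1)
        # weighted normal equations solved directly
        X = np.column_stack([np.ones(9), g])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        res = weighted_association_test(sample(g, y))
        resid = y - X @ beta
        s2 = float(w @ resid**2) / 7
        cov = s2 * np.linalg.inv(X.T @ (w[:, None] * X))
        t_oracle = beta[1] / math.sqrt(cov[1, 1])
        assert res.valid
        assert res.statistic == pytest.approx(t_oracle, rel=1e-10)

    def test_matches_statsmodels_wls(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        g = rng.integers(0, 3, 60)
        y = rng.normal(size=60) + 0.3 * g + np.where(g == 1, rng.normal(0, 1, 60), 0)
        w = np.empty(60)
        for code in (0, 1, 2):
            w[g == code] = 1.0 / np.var(y[g == code], ddof=1)
        fit = statsmodels.WLS(y, statsmodels.add_constant(g.astype(float)), weights=w).fit()
        res = weighted_association_test(sample(g, y))
        assert res.statistic == pytest.approx(fit.tvalues[1], rel=1e-8)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_degeneracies_flagged_invalid(self):
        # a present group with a single member
        assert not weighted_association_test(
            sample([0, 0, 1, 1, 2], [1, 2, 3, 4, 5])
        ).valid
        # zero variance in a present group
        assert not weighted_association_test(
            sample([0, 0, 1, 1], [2, 2, 3, 4])
        ).valid
        # monomorphic
        assert not weighted_association_test(
            sample([1, 1, 1, 1], [1, 2, 3, 4])
        ).valid


class TestStandardTest:
    def test_matches_statsmodels_ols(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, 50)
        y = rng.normal(size=50) + 0.2 * g
        fit = statsmodels.OLS(y, statsmodels.add_constant(g.astype(float))).fit()
        res = standard_association_test(sample(g, y))
        assert res.statistic == pytest.approx(fit.tvalues[1], rel=1e-8)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_perfect_fit_reports_zero_p(self):
        res = standard_association_test(sample([0, 1, 2, 1], [0.0, 2.0, 4.0, 2.0]))
        assert res.valid
        assert res.p_value == 0.0
        assert res.direction == 1

    def test_monomorphic_invalid(self):
        assert not standard_association_test(sample([2, 2, 2], [1, 2, 3])).valid

    def test_equal_group_variances_collapse_to_weighted(self):
        # three groups with identical empirical variance -> WLS == OLS
        s = sample([0, 0, 1, 1, 2, 2], [0.0, 2.0, 5.0, 7.0, 9.0, 11.0])
        ols = standard_association_test(s)
        wls = weighted_association_test(s)
        assert ols.statistic == pytest.approx(wls.statistic, rel=1e-12)
        assert ols.p_value == pytest.approx(wls.p_value, rel=1e-12)


class TestStouffer:
    def test_null_components_stay_null(self):
        assert stouffer_combine(0.5, 0.5) == pytest.approx(0.5)

    def test_symmetry_and_degenerate_weight(self):
        assert stouffer_combine(0.01, 0.3) == pytest.approx(stouffer_combine(0.3, 0.01))
        assert stouffer_combine(0.07, 0.9, w1=1.0, w2=0.0) == pytest.approx(0.07)

    def test_extreme_p_clamped_not_crashing(self):
        assert 0.0 <= stouffer_combine(0.0, 0.5) < 1e-6
        assert 0.0 < stouffer_combine(1.0, 0.5) <= 1.0

    def test_rejects_bad_weights(self):
        with pytest.raises(ValueError):
            stouffer_combine(0.5, 0.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            stouffer_combine(0.5, 0.5, -1.0, 1.0)


class TestCombinedTest:
    def test_equals_stouffer_of_components(self):
        rng = np.random.default_rng(3)
        s = sample(rng.integers(0, 3, 200), rng.normal(size=200))
        res = combined_test(s)
        expected = stouffer_combine(
            variance_test(s).p_value, weighted_association_test(s).p_value
        )
        assert res.valid
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_component_invalidity_propagates(self):
        res = combined_test(sample([1, 1, 1], [1.0, 2.0, 3.0]))
        assert not res.valid
        assert res.p_value is None


@pytest.mark.parametrize("shift", [-17.3, 4.0, 1e4])
def test_location_invariance_of_all_tests(shift):
    """Adding a constant to every phenotype leaves all four p-values unchanged."""
    rng = np.random.default_rng(11)
    g = rng.integers(0, 3, 300)
    y = rng.normal(size=300) + 0.1 * g
    s0, s1 = sample(g, y), sample(g, y + shift)
    for test in (
        variance_test,
        weighted_association_test,
        standard_association_test,
        combined_test,
    ):
        assert test(s0).p_value == pytest.approx(test(s1).p_value, rel=1e-6, abs=1e-9)


@pytest.mark.parametrize("scale", [0.01, 3.0, 250.0])
def test_scale_invariance_of_variance_test(scale):
    """Multiplying phenotypes by c > 0 leaves the variance statistic unchanged."""
    rng = np.random.default_rng(13)
    g = rng.integers(0, 3, 300)
    y = rng.normal(size=300)
    r0, r1 = variance_test(sample(g, y)), variance_test(sample(g, y * scale))
    assert r0.statistic == pytest.approx(r1.statistic, rel=1e-9)
    assert r0.p_value == pytest.approx(r1.p_value, rel=1e-9)
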
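"""Wald ratios, IVW, MR-Egger, weighted median and OR rendering."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from cytomr.errors import ValidationError
from cytomr.estimators import (
    Z95,
    egger,
    ivw,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
)

from conftest import make_harmonized


class TestWaldRatios:
    def test_unit_denominator(self):
        h = make_harmonized([1.0], [0.05], outcome_se=0.02)
        r = wald_ratios(h)
        assert r["ratio"].iloc[0] == pytest.approx(0.05)
        assert r["se"].iloc[0] == pytest.approx(0.02)

    def test_delta_formula(self):
        h = make_harmonized([0.2], [0.05], outcome_se=0.02)
        r = wald_ratios(h)
        assert r["ratio"].iloc[0] == pytest.approx(0.25)
        assert r["se"].iloc[0] == pytest.approx(0.10)
        assert r["weight"].iloc[0] == pytest.approx(0.10**-2)

    def test_sign_carried_through_negative_gamma(self):
        h = make_harmonized([-0.2], [0.05], outcome_se=0.02)
        r = wald_ratios(h)
        assert r["ratio"].iloc[0] == pytest.approx(-0.25)
        assert r["se"].iloc[0] == pytest.approx(0.10)

    def test_zero_gamma_names_snp(self):
        h = make_harmonized([0.1, 0.0], [0.05, 0.05])
        with pytest.raises(ValidationError, match="rs2"):
            wald_ratios(h)

    def test_second_order_se_is_larger(self):
        h = make_harmonized([0.2], [0.05], exposure_se=0.05, outcome_se=0.02)
        first = wald_ratios(h)["se"].iloc[0]
        second = wald_ratios(h, second_order=True)["se"].iloc[0]
        assert second > first

    def test_dropped_rows_never_enter(self):
        h = make_harmonized([0.2, 0.2], [0.05, 99.0])
        h.loc[1, "action"] = "dropped"
        assert len(wald_ratios(h)) == 1


class TestIvw:
    def test_closed_form_weighted_mean(self):
        # equal ses: beta is the plain mean, se = se/sqrt(J)
        h = make_harmonized([1.0, 1.0, 1.0], [0.10, 0.20, 0.30], outcome_se=0.1)
        est, q = ivw(h, mode="fixed")
        assert est.beta == pytest.approx(0.20)
        assert est.se == pytest.approx(0.1 / np.sqrt(3))
        assert q.df == 2

    def test_single_instrument_degenerates_to_wald_ratio(self):
        h = make_harmonized([0.2], [0.05], outcome_se=0.02)
        est, q = ivw(h)
        assert est.beta == pytest.approx(0.25)
        assert est.se == pytest.approx(0.10)
        assert est.method == "IVW-fixed"
        assert q is None

    def test_zero_instruments_structured_empty(self):
        h = make_harmonized([0.2], [0.05], action="dropped")
        est, q = ivw(h)
        assert est.is_empty
        assert np.isnan(est.beta)

    def test_homogeneous_set_auto_stays_fixed(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.2, 0.2, 0.2], outcome_se=0.1)
        est, q = ivw(h, mode="auto")
        assert q.q == pytest.approx(0.0)
        assert q.pval == pytest.approx(1.0)
        assert est.method == "IVW-fixed"

    def test_auto_switches_to_random_under_heterogeneity(self):
        h = make_harmonized([1.0] * 4, [0.0, 0.0, 1.0, 1.0], outcome_se=0.05)
        est_auto, q = ivw(h, mode="auto")
        est_fixed, _ = ivw(h, mode="fixed")
        assert q.pval < 0.05
        assert est_auto.method == "IVW-random"
        assert est_auto.se == pytest.approx(est_fixed.se * np.sqrt(q.q / 3))
        assert est_auto.beta == pytest.approx(est_fixed.beta)

    def test_random_never_deflates_below_fixed(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.2, 0.2, 0.2], outcome_se=0.1)
        est_r, _ = ivw(h, mode="random")
        est_f, _ = ivw(h, mode="fixed")
        assert est_r.se == est_f.se  # Q=0: max(1, .) clamps at 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_zero_intercept_weighted_regression(self, seed):
        """IVW-fixed is the no-intercept WLS slope of Gamma on gamma
        with weights 1/outcome_se^2 (algebraic identity)."""
        rng = np.random.default_rng(seed)
        j = rng.integers(3, 12)
        gamma = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
        big_gamma = 0.2 * gamma + rng.normal(0, 0.02, j)
        s_y = rng.uniform(0.01, 0.05, j)
        h = make_harmonized(gamma, big_gamma, outcome_se=s_y)
        est, _ = ivw(h, mode="fixed")
        fit = sm.WLS(big_gamma, gamma[:, None], weights=1 / s_y**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_ci_and_pval_consistent(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], outcome_se=0.1)
        est, _ = ivw(h, mode="fixed")
        assert est.ci_low == pytest.approx(est.beta - Z95 * est.se)
        assert est.pval == pytest.approx(2 * sps.norm.sf(abs(est.beta) / est.se))


class TestEgger:
    def test_fewer_than_three_instruments_rejected(self):
        h = make_harmonized([0.2, 0.3], [0.1, 0.15])
        with pytest.raises(ValidationError, match="3"):
            egger(h)

    def test_exact_linear_toy_set(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(gamma, 0.5 * gamma + 0.03, outcome_se=0.02)
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.estimate == pytest.approx(0.03, abs=1e-10)

    def test_orientation_invariance(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        big_gamma = 0.5 * gamma + 0.03
        s1, i1 = egger(make_harmonized(gamma, big_gamma, outcome_se=0.02))
        s2, i2 = egger(make_harmonized(-gamma, -big_gamma, outcome_se=0.02))
        assert s2.beta == pytest.approx(s1.beta)
        assert i2.estimate == pytest.approx(i1.estimate)
        assert s2.se == pytest.approx(s1.se)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_weighted_normal_equations(self, seed):
        """Oracle: solve (X'WX) b = X'WY explicitly, with SEs from
        (X'WX)^-1 scaled by max(1, sqrt(Q/(J-2)))."""
        rng = np.random.default_rng(seed)
        j = int(rng.integers(4, 10))
        gamma = rng.uniform(0.05, 0.5, j)
        big_gamma = 0.3 * gamma + 0.02 + rng.normal(0, 0.03, j)
        s_y = rng.uniform(0.01, 0.05, j)
        w = 1 / s_y**2
        x = np.column_stack([np.ones(j), gamma])
        xtwx = x.T @ (w[:, None] * x)
        xtwy = x.T @ (w * big_gamma)
        coef = np.linalg.solve(xtwx, xtwy)
        resid = big_gamma - x @ coef
        q = np.sum(w * resid**2)
        disp = max(1.0, np.sqrt(q / (j - 2)))
        se = np.sqrt(np.diag(np.linalg.inv(xtwx))) * disp

        slope, intercept = egger(make_harmonized(gamma, big_gamma, outcome_se=s_y))
        assert slope.beta == pytest.approx(coef[1], abs=1e-10)
        assert intercept.estimate == pytest.approx(coef[0], abs=1e-10)
        assert slope.se == pytest.approx(se[1], abs=1e-10)
        assert intercept.se == pytest.approx(se[0], abs=1e-10)
        assert intercept.pval == pytest.approx(
            2 * sps.t.sf(abs(coef[0]) / se[0], j - 2), abs=1e-12
        )


class TestWeightedMedian:
    def test_identical_ratios_regardless_of_weights(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.2, 0.2, 0.2],
                            outcome_se=[0.01, 0.1, 0.5])
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_middle_crossing_equal_weights(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], outcome_se=0.1)
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_interpolation_oracle(self, seed):
        """Oracle: np.interp of 0.5 on the centered cumulative
        standardized weights over the sorted ratios."""
        rng = np.random.default_rng(seed)
        j = int(rng.integers(3, 15))
        ratio = rng.normal(0.1, 0.3, j)
        s = rng.uniform(0.02, 0.2, j)
        h = make_harmonized(np.ones(j), ratio, outcome_se=s)
        est = weighted_median(h, n_boot=100, seed=1)
        order = np.argsort(ratio)
        b, w = ratio[order], (1 / s**2)[order]
        p = (np.cumsum(w) - 0.5 * w) / w.sum()
        assert est.beta == pytest.approx(np.interp(0.5, p, b), abs=1e-10)

    def test_breakdown_under_minority_invalid_weight(self):
        """10 instruments, 4 with a +1.0 pleiotropic ratio offset but
        minority weight: the estimate stays near the clean 0.1."""
        ratio = np.array([0.1] * 6 + [1.1] * 4)
        se = np.array([0.02] * 6 + [0.2] * 4)
        h = make_harmonized(np.ones(10), ratio, outcome_se=se)
        est = weighted_median(h, n_boot=500, seed=5)
        assert abs(est.beta - 0.1) < 2 * est.se

    def test_seed_reproducibility_and_boot_warning(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], outcome_se=0.1)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a == b
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(h, n_boot=50, seed=0)

    def test_fewer_than_three_rejected(self):
        h = make_harmonized([1.0, 1.0], [0.1, 0.2])
        with pytest.raises(ValidationError):
            weighted_median(h, seed=0)


class TestOddsRatio:
    def test_null_beta_gives_unit_or(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], outcome_se=0.1)
        est, _ = ivw(h, mode="fixed")
        rendered = to_odds_ratio(est)
        assert rendered.odds_ratio == pytest.approx(1.0)
        assert rendered.ci_low == pytest.approx(np.exp(-Z95 * est.se))
        assert rendered.ci_high == pytest.approx(np.exp(Z95 * est.se))

    def test_published_style_rendering(self):
        """beta/se back-derived from a printed OR of 1.115 with 95% CI
        (1.024, 1.215) must render to the same three-decimal string."""
        lo, hi = np.log(1.024), np.log(1.215)
        beta, se = (lo + hi) / 2, (hi - lo) / (2 * Z95)
        from cytomr.estimators import MrEstimate

        est = MrEstimate("IVW-fixed", beta, se, beta - Z95 * se, beta + Z95 * se,
                         0.013, 8)
        assert str(to_odds_ratio(est)) == "1.115 (1.024–1.215)"

    def test_negation_gives_reciprocal_with_swapped_ci(self):
        from cytomr.estimators import MrEstimate

        est = MrEstimate("IVW-fixed", 0.2, 0.05, 0.2 - Z95 * 0.05,
                         0.2 + Z95 * 0.05, 0.01, 5)
        neg = MrEstimate("IVW-fixed", -0.2, 0.05, -0.2 - Z95 * 0.05,
                         -0.2 + Z95 * 0.05, 0.01, 5)
        a, b = to_odds_ratio(est), to_odds_ratio(neg)
        assert b.odds_ratio == pytest.approx(1 / a.odds_ratio)
        assert b.ci_low == pytest.approx(1 / a.ci_high)
        assert b.ci_high == pytest.approx(1 / a.ci_low)
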
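import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm

from langbias import (DesignMatrix, ValidationError, fit_firth, fit_mle,
                      fit_mle_2x2, plr_pvalue, profile_ci)
from langbias.firth_logistic import _penalized_loglik

import pandas as pd


SEPARATED_X = np.column_stack([np.ones(8), [0, 0, 0, 0, 1, 1, 1, 1.0]])
SEPARATED_Y = np.array([0, 0, 1, 0, 1, 1, 1, 1], dtype=float)  # x=1 -> y=1


def _grid_argmax(X, y, lo=-10.0, hi=10.0):
    """Coarse-to-fine grid maximization of the penalized likelihood over a
    two-coefficient design: the independent Firth oracle."""
    best = None
    b0 = np.arange(lo, hi + 1e-9, 0.05)
    b1 = np.arange(lo, hi + 1e-9, 0.05)
    for a in b0:
        for b in b1:
            ll = _penalized_loglik(X, y, np.array([a, b]), firth=True)
            if best is None or ll > best[0]:
                best = (ll, a, b)
    _, a0, a1 = best
    fine = None
    for a in np.arange(a0 - 0.05, a0 + 0.05, 0.0005):
        for b in np.arange(a1 - 0.05, a1 + 0.05, 0.0005):
            ll = _penalized_loglik(X, y, np.array([a, b]), firth=True)
            if fine is None or ll > fine[0]:
                fine = (ll, a, b)
    return np.array(fine[1:])


class TestFitFirth:
    def test_separated_data_finite_and_matches_grid_oracle(self):
        fit = fit_firth(SEPARATED_X, SEPARATED_Y, ci="wald")
        assert all(np.isfinite(fit.beta))
        oracle = _grid_argmax(SEPARATED_X, SEPARATED_Y)
        assert fit.beta[0] == pytest.approx(oracle[0], abs=1e-3)
        assert fit.beta[1] == pytest.approx(oracle[1], abs=1e-3)

    def test_mle_diverges_on_the_same_data(self):
        fit = fit_mle(SEPARATED_X, SEPARATED_Y)
        assert not fit.converged
        assert abs(fit.beta[1]) > 10

    @pytest.mark.parametrize("events,n", [(3, 10), (0, 7), (12, 12), (5, 40)])
    def test_intercept_only_closed_form(self, events, n):
        # penalized binomial: pi_hat = (k + 1/2) / (n + 1)
        y = np.array([1.0] * events + [0.0] * (n - events))
        if events in (0, n):
            with pytest.raises(ValidationError):
                fit_firth(np.ones((n, 1)), y, ci="wald")
            return
        fit = fit_firth(np.ones((n, 1)), y, ci="wald")
        assert expit(fit.beta[0]) == pytest.approx((events + 0.5) / (n + 1),
                                                   abs=1e-8)

    def test_null_simulation_slope_near_zero(self, rng):
        n = 4000
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_firth(np.column_stack([np.ones(n), x]), y, ci="wald")
        assert abs(fit.beta[1]) < 0.1

    def test_firth_approaches_mle_without_separation(self, rng):
        n = 5000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        f = fit_firth(X, y, ci="wald")
        m = fit_mle(X, y)
        assert m.converged
        assert abs(f.beta[1] - m.beta[1]) < 0.02

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"intercept": np.ones(6), "a": [0, 1, 0, 1, 0, 1],
                          "b": [0, 2, 0, 2, 0, 2]})
        with pytest.raises(ValidationError, match="collinear"):
            DesignMatrix(columns=X, response=np.array([0, 1, 0, 1, 1, 0.0]))


class TestProfileCI:
    def test_symmetric_table_gives_symmetric_interval(self):
        # equal cells: the penalized likelihood is symmetric in the slope
        X = np.column_stack([np.ones(8), [0, 0, 0, 0, 1, 1, 1, 1.0]])
        y = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=float)
        fit = fit_firth(X, y, ci="wald")
        lo, hi = profile_ci(X, y, fit, 1)
        assert lo == pytest.approx(-hi, abs=1e-4)

    def test_separated_table_has_finite_interval(self):
        fit = fit_firth(SEPARATED_X, SEPARATED_Y, ci="profile")
        assert math.isfinite(fit.ci_low[1]) and math.isfinite(fit.ci_high[1])
        assert fit.ci_low[1] < fit.beta[1] < fit.ci_high[1]

    def test_higher_level_interval_contains_lower(self):
        fit = fit_firth(SEPARATED_X, SEPARATED_Y, ci="wald")
        lo90, hi90 = profile_ci(SEPARATED_X, SEPARATED_Y, fit, 1, level=0.90)
        lo95, hi95 = profile_ci(SEPARATED_X, SEPARATED_Y, fit, 1, level=0.95)
        assert lo95 < lo90 < hi90 < hi95

    def test_interval_endpoints_sit_on_the_likelihood_threshold(self):
        fit = fit_firth(SEPARATED_X, SEPARATED_Y, ci="wald")
        lo, hi = profile_ci(SEPARATED_X, SEPARATED_Y, fit, 1)
        thresh = stats.chi2.ppf(0.95, 1)
        for bound in (lo, hi):
            beta = np.array(fit.beta)
            # profile out the intercept on a fine local grid
            lls = [_penalized_loglik(SEPARATED_X, SEPARATED_Y,
                                     np.array([b0, bound]), firth=True)
                   for b0 in np.arange(beta[0] - 4, beta[0] + 4, 0.001)]
            drop = 2 * (fit.loglik - max(lls))
            assert drop == pytest.approx(thresh, abs=1e-2)


class TestPLRPValue:
    def test_duality_with_profile_interval(self, rng):
        """p < 0.05 exactly when the 95% profile CI excludes zero, on a
        battery of random small datasets including near-boundary ones."""
        for _ in range(25):
            n = int(rng.integers(12, 40))
            x = rng.normal(size=n)
            y = (rng.random(n) < expit(rng.normal(0, 1) * x)).astype(float)
            if y.sum() in (0, n):
                continue
            X = np.column_stack([np.ones(n), x])
            fit = fit_firth(X, y, ci="wald")
            p = plr_pvalue(X, y, fit, 1)
            lo, hi = profile_ci(X, y, fit, 1)
            assert (p < 0.05) == (lo > 0 or hi < 0)

    def test_null_pvalues_approximately_uniform(self, rng):
        pvals = []
        for _ in range(1000):
            n = 40
            x = rng.normal(size=n)
            y = (rng.random(n) < 0.5).astype(float)
            if y.sum() in (0, n):
                continue
            X = np.column_stack([np.ones(n), x])
            fit = fit_firth(X, y, ci="wald")
            pvals.append(plr_pvalue(X, y, fit, 1))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_intercept_pvalue_only_duality_is_claimed(self):
        X = np.column_stack([np.ones(8), [0, 0, 0, 0, 1, 1, 1, 1.0]])
        y = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=float)
        fit = fit_firth(X, y, ci="wald")
        p = plr_pvalue(X, y, fit, 0)
        lo, hi = profile_ci(X, y, fit, 0)
        assert (p < 0.05) == (lo > 0 or hi < 0)


class TestMle2x2:
    def test_published_counts_reproduce_cross_product_ratio(self):
        fit = fit_mle_2x2(16, 4, 5, 4)
        assert fit.or_[1] == pytest.approx(3.20, abs=0.005)
        assert fit.or_[1] == pytest.approx((16 * 4) / (4 * 5), rel=1e-12)

    def test_uniform_table_gives_no_association(self):
        fit = fit_mle_2x2(7, 7, 7, 7)
        assert fit.or_[1] == pytest.approx(1.0, rel=1e-12)

    def test_matches_iterative_logistic_fit(self):
        a, b, c, d = 1, 1, 1, 2
        fit = fit_mle_2x2(a, b, c, d)
        assert fit.or_[1] == pytest.approx(2.0, rel=1e-12)
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
        sm_fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.beta[1] == pytest.approx(sm_fit.params[1], abs=1e-8)
        assert fit.beta[0] == pytest.approx(sm_fit.params[0], abs=1e-8)

    def test_zero_cell_directs_to_firth(self):
        with pytest.raises(ValidationError, match="fit_firth"):
            fit_mle_2x2(5, 0, 3, 2)
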
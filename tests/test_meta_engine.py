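import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from langbias import (EffectEstimate, ValidationError, meta_regress,
                      pool_fixed, pool_random, tau2_dl, tau2_reml)
from langbias.meta_engine import _neg_restricted_ll


def eff(pairs):
    return [EffectEstimate(y, v) for y, v in pairs]


def _grid_reml(effects, design=None, upper=10.0, step=1e-4):
    """Dense grid search over tau^2: the independent REML oracle."""
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    X = np.ones((len(y), 1)) if design is None else np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    grid = np.arange(0.0, upper + step, step)
    vals = [_neg_restricted_ll(t, y, v, X) for t in grid]
    return float(grid[int(np.argmin(vals))])


class TestPoolFixed:
    def test_equal_variance_average(self):
        p = pool_fixed(eff([(0.2, 0.04), (0.6, 0.04)]))
        assert p.mu == pytest.approx(0.4, abs=1e-15)
        assert p.se == pytest.approx(math.sqrt(0.02), abs=1e-15)

    def test_identical_effects_no_heterogeneity(self):
        p = pool_fixed(eff([(0.3, 0.01), (0.3, 0.05), (0.3, 0.2)]))
        assert p.mu == pytest.approx(0.3, abs=1e-15)
        assert p.het.Q == pytest.approx(0.0, abs=1e-12)
        assert p.het.I2 == 0.0

    def test_matches_weighted_average_oracle(self, rng):
        y = rng.normal(0, 1, 5)
        v = rng.uniform(0.01, 0.5, 5)
        p = pool_fixed(eff(list(zip(y, v))))
        w = 1 / v
        assert p.mu == pytest.approx(float(w @ y / w.sum()), abs=1e-12)
        assert p.se == pytest.approx(math.sqrt(1 / w.sum()), abs=1e-12)

    def test_single_effect_rejected(self):
        with pytest.raises(ValidationError):
            pool_fixed(eff([(0.1, 0.1)]))


class TestTau2DL:
    def test_homogeneous_truncates_to_zero(self):
        assert tau2_dl(eff([(0.2, 0.1), (0.2, 0.1), (0.2, 0.1)])) == 0.0

    def test_hand_computed_two_study_value(self):
        # w = (1,1): Q = 2, df = 1, denominator = 2 - 2/2 = 1 -> tau2 = 1
        assert tau2_dl(eff([(0.0, 1.0), (2.0, 1.0)])) == pytest.approx(1.0, abs=1e-14)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 10))
    def test_variance_rescaling_consistent_with_formula(self, c):
        base = [(0.0, 0.05), (1.0, 0.04), (2.0, 0.05), (0.4, 0.04)]
        t_base = tau2_dl(eff(base))
        t_scaled = tau2_dl(eff([(y, c * v) for y, v in base]))
        # recompute the moment formula directly at scaled variances
        y = np.array([p[0] for p in base])
        v = c * np.array([p[1] for p in base])
        w = 1 / v
        mu = w @ y / w.sum()
        Q = w @ (y - mu) ** 2
        expected = max(0.0, (Q - (len(y) - 1)) / (w.sum() - w @ w / w.sum()))
        assert t_scaled == pytest.approx(expected, rel=1e-10)
        assert t_base > 0  # the base set really is heterogeneous


class TestTau2REML:
    def test_equal_variances_match_dense_grid(self):
        effects = eff([(0.0, 0.05), (0.5, 0.05), (1.0, 0.05), (1.5, 0.05)])
        est = tau2_reml(effects)
        grid = _grid_reml(effects)
        assert est == pytest.approx(grid, abs=1e-4)

    def test_moderator_design_matches_dense_grid(self):
        effects = eff([(0.0, 0.03), (0.9, 0.05), (0.2, 0.04), (1.4, 0.06),
                       (0.1, 0.03), (1.1, 0.05)])
        X = np.column_stack([np.ones(6), [0, 1, 0, 1, 0, 1]])
        est = tau2_reml(effects, design=X)
        assert est == pytest.approx(_grid_reml(effects, X), abs=1e-4)

    def test_zero_heterogeneity_data_estimates_near_zero(self, rng):
        medians = []
        for _ in range(30):
            v = rng.uniform(0.01, 0.05, 60)
            y = rng.normal(0.3, np.sqrt(v))
            medians.append(tau2_reml(eff(list(zip(y, v)))))
        assert np.median(medians) < 0.01

    def test_recovers_injected_heterogeneity(self, rng):
        tau = 0.3
        v = rng.uniform(0.01, 0.05, 200)
        y = rng.normal(0.3, np.sqrt(v + tau ** 2))
        est = tau2_reml(eff(list(zip(y, v))))
        # k = 200: REML standard error of tau2 is roughly tau2*sqrt(2/k)
        assert est == pytest.approx(tau ** 2, abs=4 * tau ** 2 * math.sqrt(2 / 200))


class TestPoolRandom:
    def test_collapses_to_fixed_at_zero_tau2(self):
        effects = eff([(0.1, 0.04), (0.4, 0.09), (0.2, 0.02)])
        pr = pool_random(effects, tau2=0.0)
        pf = pool_fixed(effects)
        assert (pr.mu, pr.se, pr.ci_low, pr.ci_high, pr.p_value) == \
               (pf.mu, pf.se, pf.ci_low, pf.ci_high, pf.p_value)

    def test_random_se_never_below_fixed(self):
        effects = eff([(0.0, 0.02), (1.0, 0.03), (2.0, 0.02), (-0.5, 0.05)])
        assert pool_random(effects).se >= pool_fixed(effects).se

    def test_equal_variances_give_unweighted_mean(self):
        effects = eff([(0.1, 0.04), (0.5, 0.04), (0.9, 0.04)])
        for method in ("reml", "dl"):
            assert pool_random(effects, tau2_method=method).mu == \
                   pytest.approx(0.5, abs=1e-10)

    def test_knapp_hartung_uses_t_quantiles(self):
        effects = eff([(0.0, 0.02), (1.0, 0.03), (2.0, 0.02), (-0.5, 0.05)])
        plain = pool_random(effects)
        kh = pool_random(effects, knapp_hartung=True)
        assert kh.ci_high - kh.ci_low != pytest.approx(
            plain.ci_high - plain.ci_low)


class TestMetaRegress:
    def test_saturated_two_group_means(self):
        effects = eff([(0.0, 0.04), (0.0, 0.04), (0.5, 0.04)])
        beta, cov, het = meta_regress(effects, [0, 0, 1], tau2=0.0)
        assert beta[0] == pytest.approx(0.0, abs=1e-12)
        assert beta[1] == pytest.approx(0.5, abs=1e-12)

    def test_slope_location_invariant(self):
        effects = eff([(0.1, 0.02), (0.7, 0.05), (0.3, 0.03), (0.9, 0.04)])
        shifted = eff([(y + 2.5, v) for y, v in
                       [(0.1, 0.02), (0.7, 0.05), (0.3, 0.03), (0.9, 0.04)]])
        mod = [0, 1, 0, 1]
        b1, _, _ = meta_regress(effects, mod)
        b2, _, _ = meta_regress(shifted, mod)
        assert b1[1] == pytest.approx(b2[1], abs=1e-9)

    def test_constant_moderator_rejected(self):
        with pytest.raises(ValidationError, match="contrast"):
            meta_regress(eff([(0.1, 0.1), (0.2, 0.1)]), [1, 1])

    def test_intercept_only_reml_reproduces_pool_random(self):
        effects = eff([(0.0, 0.03), (0.9, 0.05), (0.2, 0.04), (1.4, 0.06)])
        tau2 = tau2_reml(effects)
        p = pool_random(effects, tau2_method="reml")
        y = np.array([e.y for e in effects])
        w = 1 / (np.array([e.v for e in effects]) + tau2)
        assert p.mu == pytest.approx(float(w @ y / w.sum()), abs=1e-12)


def test_three_study_worked_example_hand_values():
    """Q, I-squared and the moment tau2 on a 3-study set, against values
    carried through by hand with exact weights."""
    effects = eff([(0.2, 0.04), (0.5, 0.05), (1.0, 0.10)])
    w = np.array([25.0, 20.0, 10.0])
    y = np.array([0.2, 0.5, 1.0])
    mu = float(w @ y / w.sum())            # (5 + 10 + 10) / 55
    Q = float(w @ (y - mu) ** 2)
    I2 = max(0.0, (Q - 2) / Q) * 100
    denom = w.sum() - float(w @ w) / w.sum()
    tau2 = max(0.0, (Q - 2) / denom)
    p = pool_fixed(effects)
    assert p.mu == pytest.approx(mu, abs=1e-10)
    assert p.het.Q == pytest.approx(Q, abs=1e-10)
    assert p.het.I2 == pytest.approx(I2, abs=1e-10)
    assert tau2_dl(effects) == pytest.approx(tau2, abs=1e-10)


def test_agrees_with_metafor_reference():
    """Independent cross-check of REML/DL meta-regression against the
    reference R implementation (metafor::rma)."""
    rng = np.random.default_rng(3)
    y = rng.normal(0.3, 0.6, 10)
    v = rng.uniform(0.01, 0.05, 10)
    mod = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1], dtype=float)
    effects = eff(list(zip(y, v)))
    beta, cov, het = meta_regress(effects, mod, "reml")
    beta_dl, _, het_dl = meta_regress(effects, mod, "dl")
    script = (
        "suppressMessages(library(metafor));"
        f"y <- c({','.join(repr(float(x)) for x in y)});"
        f"v <- c({','.join(repr(float(x)) for x in v)});"
        f"m <- c({','.join(repr(float(x)) for x in mod)});"
        "f <- rma(y, v, mods=~m, method='REML', control=list(tol=1e-12));"
        "fd <- rma(y, v, mods=~m, method='DL');"
        "cat(sprintf('%.10f %.10f %.10f %.10f %.10f', coef(f)[2], f$se[2],"
        " f$tau2, coef(fd)[2], fd$tau2))"
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    r_slope, r_se, r_tau2, r_slope_dl, r_tau2_dl = map(float, out.stdout.split())
    assert beta[1] == pytest.approx(r_slope, abs=1e-6)
    assert math.sqrt(cov[1, 1]) == pytest.approx(r_se, abs=1e-6)
    assert het.tau2 == pytest.approx(r_tau2, abs=1e-6)
    assert beta_dl[1] == pytest.approx(r_slope_dl, abs=1e-8)
    assert het_dl.tau2 == pytest.approx(r_tau2_dl, abs=1e-8)
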
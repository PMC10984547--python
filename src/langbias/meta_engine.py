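"""Inverse-variance pooling, heterogeneity estimation and meta-regression.

Implements the classical machinery from its defining formulas: fixed-effect
and random-effects pooling, Cochran's Q and I², the DerSimonian–Laird
moment estimator and the REML estimator of the between-study variance τ²,
and weighted least-squares meta-regression with a single additive τ².

Model: y_i ~ N(x_i' beta, v_i + tau²), with known sampling variances v_i.
Confidence intervals use normal quantiles by default; the Knapp–Hartung
small-sample adjustment (t quantiles with a scaled variance) is available
behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .data_model_io import EffectEstimate, ValidationError

__all__ = [
    "HetStats",
    "PooledEstimate",
    "pool_fixed",
    "pool_random",
    "tau2_dl",
    "tau2_reml",
    "meta_regress",
]

REML_TAU2_UPPER = 100.0
REML_XATOL = 1e-8
REML_MAXITER = 500


@dataclass(frozen=True, slots=True)
class HetStats:
    """Cochran's Q, its degrees of freedom, I² (percent) and τ²/τ."""

    Q: float
    df: int
    I2: float
    tau2: float
    tau: float


@dataclass(frozen=True, slots=True)
class PooledEstimate:
    mu: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    het: HetStats


def _as_arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.y for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return y, v


def _het_stats(y: np.ndarray, v: np.ndarray, tau2: float) -> HetStats:
    """Q/I² from fixed-effect weights; τ² as supplied by the caller."""
    w = 1.0 / v
    mu = float(w @ y / w.sum())
    Q = float(w @ (y - mu) ** 2)
    df = len(y) - 1
    # Degenerate case: identical effects give Q = 0 (guard 0/0 -> I2 = 0)
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HetStats(Q=Q, df=df, I2=I2, tau2=tau2, tau=math.sqrt(tau2))


def _pool(y: np.ndarray, v: np.ndarray, tau2: float, model: str,
          level: float, knapp_hartung: bool) -> PooledEstimate:
    w = 1.0 / (v + tau2)
    sw = w.sum()
    mu = float(w @ y / sw)
    se = math.sqrt(1.0 / sw)
    k = len(y)
    if knapp_hartung and k > 1:
        s2 = float(w @ (y - mu) ** 2) / (k - 1) / sw
        se_kh = math.sqrt(max(s2, 0.0))
        crit = stats.t.ppf(0.5 + level / 2.0, df=k - 1)
        se_used, q = se_kh, crit
        p = 2.0 * stats.t.sf(abs(mu / se_kh), df=k - 1) if se_kh > 0 else 0.0
    else:
        q = stats.norm.ppf(0.5 + level / 2.0)
        se_used = se
        p = 2.0 * stats.norm.sf(abs(mu / se))
    het = _het_stats(y, v, tau2)
    return PooledEstimate(mu=mu, se=se_used, ci_low=mu - q * se_used,
                          ci_high=mu + q * se_used, p_value=float(min(p, 1.0)),
                          model=model, het=het)


def pool_fixed(effects: Sequence[EffectEstimate], level: float = 0.95,
               knapp_hartung: bool = False) -> PooledEstimate:
    """Fixed-effect (common-effect) inverse-variance pooling."""
    if len(effects) < 2:
        raise ValidationError("pool_fixed: need at least 2 effects")
    y, v = _as_arrays(effects)
    return _pool(y, v, 0.0, "fixed", level, knapp_hartung)


def tau2_dl(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian–Laird moment estimator of τ² (intercept-only model)."""
    if len(effects) < 2:
        raise ValidationError("tau2_dl: need at least 2 effects")
    y, v = _as_arrays(effects)
    w = 1.0 / v
    sw = w.sum()
    mu = float(w @ y / sw)
    Q = float(w @ (y - mu) ** 2)
    df = len(y) - 1
    denom = sw - float(w @ w) / sw
    if denom <= 0:
        return 0.0
    return max(0.0, (Q - df) / denom)


def _tau2_dl_design(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Method-of-moments τ² generalized to a moderator design.

    Uses the residual Q from the fixed-effect weighted regression and the
    trace of the corresponding projection; reduces to DerSimonian–Laird for
    an intercept-only design.
    """
    w = 1.0 / v
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    r = y - X @ beta
    QE = float(w @ r ** 2)
    P = W - W @ X @ np.linalg.solve(XtWX, X.T @ W)
    c = float(np.trace(P))
    k, p = X.shape
    if c <= 0:
        return 0.0
    return max(0.0, (QE - (k - p)) / c)


def _neg_restricted_ll(tau2: float, y: np.ndarray, v: np.ndarray,
                       X: np.ndarray) -> float:
    """-2 x restricted log-likelihood (constant terms dropped)."""
    s = v + tau2
    w = 1.0 / s
    XtWX = X.T @ (X * w[:, None])
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return math.inf
    return float(np.log(s).sum() + logdet + w @ r ** 2)


def tau2_reml(effects: Sequence[EffectEstimate],
              design: np.ndarray | None = None) -> float:
    """REML estimate of τ² under y ~ N(X beta, v + τ²).

    One-dimensional bounded maximization of the restricted log-likelihood
    over τ² in [0, 100] (absolute tolerance 1e-8); deterministic.
    """
    y, v = _as_arrays(effects)
    k = len(y)
    X = np.ones((k, 1)) if design is None else np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < X.shape[1] + 1:
        raise ValidationError(
            f"tau2_reml: need at least {X.shape[1] + 1} effects for "
            f"{X.shape[1]} design columns, got {k}")
    res = optimize.minimize_scalar(
        _neg_restricted_ll, bounds=(0.0, REML_TAU2_UPPER), method="bounded",
        args=(y, v, X), options={"xatol": REML_XATOL, "maxiter": REML_MAXITER})
    if not res.success:
        raise ValidationError(
            f"tau2_reml: optimizer failed to converge (last iterate tau2={res.x:.6g})")
    tau2 = float(res.x)
    # The bounded search cannot land exactly on the boundary; snap to 0 when
    # the boundary is at least as good.
    if _neg_restricted_ll(0.0, y, v, X) <= res.fun:
        tau2 = 0.0
    return tau2


def _tau2_by_method(y: np.ndarray, v: np.ndarray, X: np.ndarray,
                    method: str) -> float:
    if method == "reml":
        effects = [EffectEstimate(float(a), float(b)) for a, b in zip(y, v)]
        return tau2_reml(effects, design=X)
    if method == "dl":
        return _tau2_dl_design(y, v, X)
    raise ValidationError(f"unknown tau2 method {method!r} (use 'reml' or 'dl')")


def pool_random(effects: Sequence[EffectEstimate], tau2_method: str = "reml",
                level: float = 0.95, knapp_hartung: bool = False,
                tau2: float | None = None) -> PooledEstimate:
    """Random-effects pooling with weights 1/(v_i + τ̂²).

    ``tau2`` overrides the estimator (used e.g. to force τ² = 0, under which
    the result collapses exactly to :func:`pool_fixed`).
    """
    if len(effects) < 2:
        raise ValidationError("pool_random: need at least 2 effects")
    y, v = _as_arrays(effects)
    if tau2 is None:
        X = np.ones((len(y), 1))
        tau2 = _tau2_by_method(y, v, X, tau2_method)
    if tau2 < 0:
        raise ValidationError("pool_random: tau2 must be >= 0")
    return _pool(y, v, float(tau2), "random", level, knapp_hartung)


def meta_regress(effects: Sequence[EffectEstimate],
                 moderator: Sequence[float] | np.ndarray,
                 tau2_method: str = "reml",
                 tau2: float | None = None
                 ) -> tuple[np.ndarray, np.ndarray, HetStats]:
    """Weighted meta-regression of effects on a single binary moderator.

    Design X = [1, moderator]; τ² estimated under this design by the chosen
    method (or forced via ``tau2``); beta = (X'WX)^-1 X'Wy with
    W = diag(1/(v_i + τ²)) and covariance (X'WX)^-1.  The coefficient on the
    moderator is the between-group difference in SMD.
    """
    y, v = _as_arrays(effects)
    m = np.asarray(moderator, dtype=float)
    if m.shape != y.shape:
        raise ValidationError("meta_regress: moderator length must match effects")
    if np.all(m == m[0]):
        raise ValidationError(
            "meta_regress: moderator is constant — no non-English contrast estimable")
    X = np.column_stack([np.ones_like(y), m])
    if tau2 is None:
        tau2 = _tau2_by_method(y, v, X, tau2_method)
    w = 1.0 / (v + tau2)
    XtWX = X.T @ (X * w[:, None])
    cov = np.linalg.inv(XtWX)
    beta = cov @ (X.T @ (w * y))
    het = _het_stats(y, v, float(tau2))
    return beta, cov, het
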
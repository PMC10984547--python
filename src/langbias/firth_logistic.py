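"""Bias-reduced (Firth) binary logistic regression.

Maximizes the Jeffreys-prior penalized log-likelihood

    l*(beta) = l(beta) + 1/2 log det I(beta),      I(beta) = X' W X,

with W = diag(pi_i (1 - pi_i)), via modified Fisher scoring in which each
observation's working response is shifted by h_i (1/2 - pi_i) (h_i the hat
value).  The penalty guarantees finite estimates under complete or quasi-
complete separation, where ordinary maximum likelihood diverges.

Inference follows the profile penalized likelihood: confidence bounds are
the coefficient values where twice the profile drop equals the chi-square
quantile, and p-values come from the penalized likelihood-ratio statistic.
By construction p < alpha exactly when the (1-alpha) profile CI excludes 0.

Plain maximum likelihood is the same scoring loop with the penalty off; it
backs the univariate 2x2 analysis, whose slope odds ratio equals the
cross-product ratio of the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import expit

from .data_model_io import LogisticFit, ValidationError

__all__ = [
    "DesignMatrix",
    "fit_firth",
    "fit_mle",
    "fit_mle_2x2",
    "profile_ci",
    "plr_pvalue",
]

SCORE_TOL = 1e-6
STEP_TOL = 1e-8
# modified scoring converges linearly (not quadratically) near quasi-
# separation; the cap must leave room for that tail
MAX_ITER = 300
MAX_STEP = 5.0          # per-iteration cap on any coefficient move
PROFILE_RANGE = 50.0    # log-odds range searched before a bound is flagged infinite


@dataclass
class DesignMatrix:
    """A dummy-coded design (including intercept) with a binary response."""

    columns: pd.DataFrame
    response: np.ndarray

    def __post_init__(self) -> None:
        X = self.columns.to_numpy(dtype=float)
        y = np.asarray(self.response, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValidationError("DesignMatrix: response length must match rows")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError("DesignMatrix: response must be binary 0/1")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, _, piv = linalg.qr(X, pivoting=True)
            bad = [self.columns.columns[j] for j in piv[rank:]]
            raise ValidationError(
                f"DesignMatrix: rank deficient — collinear columns {bad}")
        self.response = y

    @property
    def names(self) -> list[str]:
        return list(self.columns.columns)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.columns.to_numpy(dtype=float), self.response


def _coerce(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, DesignMatrix):
        A, resp = X.arrays()
        return A, (resp if y is None else np.asarray(y, float)), X.names
    A = np.asarray(X, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    names = [f"x{j}" for j in range(A.shape[1])]
    return A, np.asarray(y, dtype=float), names


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                      firth: bool) -> float:
    eta = X @ beta
    # log-likelihood via numerically stable log(1 + e^eta)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    if not firth:
        return ll
    pi = expit(eta)
    w = pi * (1.0 - pi)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    if sign <= 0:
        return -math.inf
    return ll + 0.5 * logdet


def _fit_core(X: np.ndarray, y: np.ndarray, firth: bool,
              fixed: dict[int, float] | None = None,
              max_iter: int = MAX_ITER
              ) -> tuple[np.ndarray, float, bool, int]:
    """Safeguarded (step-halving) modified Fisher scoring.

    ``fixed`` pins coefficients at given values; the scoring step then runs
    over the free coordinates only, while the Jeffreys penalty keeps using
    the full-design information matrix (profile penalized likelihood).
    """
    n, p = X.shape
    fixed = fixed or {}
    free = np.array([j for j in range(p) if j not in fixed], dtype=int)
    beta = np.zeros(p)
    for j, val in fixed.items():
        beta[j] = val
    ll = _penalized_loglik(X, y, beta, firth)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = expit(X @ beta)
        w = pi * (1.0 - pi)
        info = X.T @ (X * w[:, None])
        resid = y - pi
        if firth:
            try:
                M = np.linalg.solve(info, X.T * w[None, :])
            except np.linalg.LinAlgError:
                raise ValidationError("fit: singular information matrix")
            h = np.einsum("ij,ji->i", X, M)
            resid = resid + h * (0.5 - pi)
        score = X.T @ resid
        score_f = score[free]
        if len(free) == 0:
            converged = True
            break
        try:
            step = np.linalg.solve(info[np.ix_(free, free)], score_f)
        except np.linalg.LinAlgError:
            if not firth:
                # divergence under separation: weights vanish and the
                # information matrix degenerates; report non-convergence
                break
            raise ValidationError("fit: singular information matrix")
        mx = np.max(np.abs(step))
        if mx > MAX_STEP:
            step = step * (MAX_STEP / mx)
        # step-halving: never accept a decrease of the objective
        new = beta.copy()
        for _ in range(30):
            new[free] = beta[free] + step
            ll_new = _penalized_loglik(X, y, new, firth)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            ll_new = _penalized_loglik(X, y, new, firth)
        step_norm = float(np.linalg.norm(new[free] - beta[free]))
        beta, ll = new, ll_new
        if np.max(np.abs(score_f)) < SCORE_TOL and step_norm < STEP_TOL:
            converged = True
            break
    return beta, ll, converged, it


def _wald_se(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    pi = expit(X @ beta)
    w = pi * (1.0 - pi)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return np.sqrt(np.diag(cov))


def _profile_loglik(X: np.ndarray, y: np.ndarray, j: int, value: float,
                    firth: bool) -> float:
    beta, ll, conv, _ = _fit_core(X, y, firth, fixed={j: value}, max_iter=400)
    if not conv:
        # far out on the profile the information matrix flattens and scoring
        # stalls; polish with a derivative-free maximizer from the last iterate
        free = [k for k in range(X.shape[1]) if k != j]

        def neg(bf: np.ndarray) -> float:
            full = beta.copy()
            full[free] = bf
            return -_penalized_loglik(X, y, full, firth)

        res = optimize.minimize(neg, beta[free], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 20000})
        if not res.success:
            raise ValidationError(
                f"profile: inner maximization did not converge at "
                f"beta[{j}] = {value:.4g}")
        ll = -float(res.fun)
    return ll


def fit_firth(X, y=None, ci: str = "profile", level: float = 0.95) -> LogisticFit:
    """Firth bias-reduced logistic regression.

    ``ci`` selects the interval/p-value machinery: ``"profile"`` (profile
    penalized likelihood; the default and the recommended choice under
    separation) or ``"wald"``.
    """
    A, resp, names = _coerce(X, y)
    if resp.sum() == 0 or resp.sum() == len(resp):
        raise ValidationError("fit_firth: need at least one event and one non-event")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        _, _, piv = linalg.qr(A, pivoting=True)
        rank = np.linalg.matrix_rank(A)
        raise ValidationError(
            f"fit_firth: rank-deficient design (collinear columns "
            f"{[names[j] for j in piv[rank:]]})")
    beta, ll, conv, it = _fit_core(A, resp, firth=True)
    if not conv:
        raise ValidationError(f"fit_firth: no convergence within {MAX_ITER} iterations")
    p_cols = A.shape[1]
    se = _wald_se(A, beta)
    z = stats.norm.ppf(0.5 + level / 2.0)
    if ci == "wald":
        lo = beta - z * se
        hi = beta + z * se
        pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    elif ci == "profile":
        lo = np.empty(p_cols)
        hi = np.empty(p_cols)
        pvals = np.empty(p_cols)
        fit0 = LogisticFit(names, list(beta), list(np.exp(beta)),
                           [-np.inf] * p_cols, [np.inf] * p_cols,
                           [1.0] * p_cols, "firth", True, loglik=ll, n_iter=it)
        for j in range(p_cols):
            lo[j], hi[j] = profile_ci(A, resp, fit0, j, level=level)
            pvals[j] = plr_pvalue(A, resp, fit0, j)
    else:
        raise ValidationError(f"fit_firth: unknown ci type {ci!r}")
    return LogisticFit(coef_names=names, beta=list(beta), or_=list(np.exp(beta)),
                       ci_low=list(lo), ci_high=list(hi), p_values=list(pvals),
                       method="firth", converged=True, loglik=ll, n_iter=it)


def fit_mle(X, y=None, level: float = 0.95) -> LogisticFit:
    """Unpenalized maximum-likelihood logistic regression (Wald inference).

    Under separation the likelihood is monotone and the coefficients drift
    without bound; the fit is then returned with ``converged=False`` so the
    caller can fall back to :func:`fit_firth`.
    """
    A, resp, names = _coerce(X, y)
    beta, ll, conv, it = _fit_core(A, resp, firth=False)
    z = stats.norm.ppf(0.5 + level / 2.0)
    try:
        se = _wald_se(A, beta)
    except np.linalg.LinAlgError:
        se = np.full(A.shape[1], np.inf)
    with np.errstate(invalid="ignore"):
        pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return LogisticFit(coef_names=names, beta=list(beta), or_=list(np.exp(beta)),
                       ci_low=list(beta - z * se), ci_high=list(beta + z * se),
                       p_values=list(np.nan_to_num(pvals, nan=1.0)),
                       method="mle", converged=conv, loglik=ll, n_iter=it)


def profile_ci(X, y, fit: LogisticFit, j: int, level: float = 0.95
               ) -> tuple[float, float]:
    """Profile penalized-likelihood confidence bounds for coefficient j.

    Each bound solves 2 [l*(beta_hat) - max_{beta_j fixed} l*] = chi2_1
    quantile by bracketed root finding (tolerance 1e-6).  A bound is
    reported infinite only if the profile never crosses the threshold
    within +-50 on the log-odds scale.
    """
    A, resp, _ = _coerce(X, y)
    if not fit.converged:
        raise ValidationError("profile_ci: requires a converged fit")
    firth = fit.method == "firth"
    bhat = float(fit.beta[j])
    ll_hat = fit.loglik if math.isfinite(fit.loglik) else _penalized_loglik(
        A, resp, np.asarray(fit.beta, float), firth)
    thresh = stats.chi2.ppf(level, 1)

    def f(b: float) -> float:
        return 2.0 * (ll_hat - _profile_loglik(A, resp, j, b, firth)) - thresh

    se = _wald_se(A, np.asarray(fit.beta, float))[j]
    step0 = max(se, 0.25)

    def _bound(direction: float) -> float:
        prev = bhat
        step = step0
        while abs(prev - bhat) < PROFILE_RANGE:
            cand = prev + direction * step
            if f(cand) > 0.0:
                lo, hi = sorted((prev, cand))
                return float(optimize.brentq(f, lo, hi, xtol=1e-6))
            prev = cand
            step *= 1.6
        return direction * math.inf

    return _bound(-1.0), _bound(+1.0)


def plr_pvalue(X, y, fit: LogisticFit, j: int) -> float:
    """Penalized likelihood-ratio p-value for coefficient j against 0."""
    A, resp, _ = _coerce(X, y)
    if not fit.converged:
        raise ValidationError("plr_pvalue: requires a converged fit")
    firth = fit.method == "firth"
    ll_hat = fit.loglik if math.isfinite(fit.loglik) else _penalized_loglik(
        A, resp, np.asarray(fit.beta, float), firth)
    ll0 = _profile_loglik(A, resp, j, 0.0, firth)
    stat = max(0.0, 2.0 * (ll_hat - ll0))
    return float(stats.chi2.sf(stat, 1))


def fit_mle_2x2(a: int, b: int, c: int, d: int, level: float = 0.95) -> LogisticFit:
    """Univariate logistic regression on a 2x2 table (saturated model).

    Cells: ``a``/``b`` events/non-events in the exposed group, ``c``/``d``
    events/non-events in the unexposed group.  The slope odds ratio equals
    the cross-product ratio (a d)/(b c) exactly; Wald CI and p-value are
    reported.  Any zero cell makes the MLE non-finite — use
    :func:`fit_firth` instead.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValidationError("fit_mle_2x2: cells must be nonnegative integers")
    if min(cells) == 0:
        raise ValidationError(
            "fit_mle_2x2: zero cell — maximum likelihood diverges; use fit_firth")
    b0 = math.log(c / d)
    b1 = math.log((a * d) / (b * c))
    se0 = math.sqrt(1 / c + 1 / d)
    se1 = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    beta = [b0, b1]
    se = [se0, se1]
    pv = [2.0 * stats.norm.sf(abs(bb / ss)) for bb, ss in zip(beta, se)]
    # saturated-model log-likelihood at the MLE
    n1, n0 = a + b, c + d
    ll = (a * math.log(a / n1) + b * math.log(b / n1)
          + c * math.log(c / n0) + d * math.log(d / n0))
    return LogisticFit(coef_names=["intercept", "exposure"],
                       beta=beta, or_=[math.exp(b0), math.exp(b1)],
                       ci_low=[bb - z * ss for bb, ss in zip(beta, se)],
                       ci_high=[bb + z * ss for bb, ss in zip(beta, se)],
                       p_values=pv, method="mle", converged=True, loglik=ll)
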
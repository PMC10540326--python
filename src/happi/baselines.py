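"""Comparator tests that ignore genome quality.

Both baselines model the *observed* presence indicator directly with
ordinary (unpenalized) logistic regression:

* ``glm_lrt`` — likelihood-ratio test between the full and constrained
  logistic fits;
* ``glm_rao`` — Rao score test evaluated at the constrained fit, the
  procedure used by common pangenomics enrichment software.

Quality variables play no role here by definition; passing them as
covariates is the caller's explicit choice.  Separated fits are flagged
(``converged=False``) and the statistic is computed from a capped fit
rather than "fixed", matching standard GLM software behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.linalg import null_space
from scipy.special import expit
from scipy.stats import chi2

from .em import TestResult, TestSpec

__all__ = ["glm_lrt", "glm_rao", "GlmFit"]

_CAP = 15.0  # |coefficient| bound for the fallback fit under separation


@dataclass
class GlmFit:
    params: np.ndarray
    loglik: float
    fitted: np.ndarray
    converged: bool
    separated: bool


def _bernoulli_loglik(y, mu):
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _capped_newton(y, X, offset):
    """Bounded ML logistic fit used when IRLS diverges under separation."""
    from scipy.optimize import minimize

    def nll(b):
        eta = offset + X @ b
        return -float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def grad(b):
        return -(X.T @ (y - expit(offset + X @ b)))

    k = X.shape[1]
    res = minimize(nll, np.zeros(k), jac=grad, method="L-BFGS-B",
                   bounds=[(-_CAP, _CAP)] * k)
    params = res.x
    mu = expit(offset + X @ params)
    return GlmFit(params=params, loglik=_bernoulli_loglik(y, mu), fitted=mu,
                  converged=False, separated=True)


def _fit_logistic(y, X, offset=None) -> GlmFit:
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    off = np.zeros(y.size) if offset is None else np.asarray(offset, dtype=float)
    if X.shape[1] == 0:
        mu = expit(off)
        return GlmFit(params=np.zeros(0), loglik=_bernoulli_loglik(y, mu),
                      fitted=mu, converged=True, separated=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial(), offset=off)
            res = model.fit(maxiter=200)
        params = np.asarray(res.params, dtype=float)
        mu = np.asarray(res.mu, dtype=float)
        separated = bool(np.max(np.abs(params)) > _CAP) or bool(
            np.any((mu < 1e-10) | (mu > 1 - 1e-10))
        )
        if separated:
            return _capped_newton(y, X, off)
        return GlmFit(params=params, loglik=_bernoulli_loglik(y, mu), fitted=mu,
                      converged=bool(getattr(res, "converged", True)),
                      separated=False)
    except Exception:
        return _capped_newton(y, X, off)


def _reduced_design(X, spec: TestSpec):
    beta0, *_ = np.linalg.lstsq(spec.A, spec.c, rcond=None)
    N = null_space(spec.A)
    return X @ N, X @ beta0


def glm_lrt(Y_gene, X, spec: TestSpec) -> TestResult:
    """Logistic-regression likelihood-ratio test of ``A beta = c``."""
    y = np.asarray(Y_gene, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    full = _fit_logistic(y, X)
    X_red, offset = _reduced_design(X, spec)
    null = _fit_logistic(y, X_red, offset=offset)
    Q = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = float(chi2.sf(Q, df=spec.h))
    res = TestResult(Q_lrt=Q, p_value=p, method="glm-lrt", df=spec.h)
    res.converged = full.converged and null.converged  # type: ignore[attr-defined]
    res.separated = full.separated or null.separated  # type: ignore[attr-defined]
    return res


def glm_rao(Y_gene, X, spec: TestSpec) -> TestResult:
    """Rao score test of ``A beta = c`` at the constrained logistic fit.

    ``Q = U0' I0^{-1} U0`` with score and expected information of the full
    model evaluated at the null estimate.  On a 2x2 layout this statistic
    coincides with the Pearson chi-square.
    """
    y = np.asarray(Y_gene, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    X_red, offset = _reduced_design(X, spec)
    null = _fit_logistic(y, X_red, offset=offset)
    mu0 = np.clip(null.fitted, 1e-12, 1.0 - 1e-12)
    U = X.T @ (y - mu0)
    W = mu0 * (1.0 - mu0)
    info = X.T @ (X * W[:, None])
    try:
        Q = float(U @ np.linalg.solve(info, U))
    except np.linalg.LinAlgError:
        Q = float(U @ np.linalg.pinv(info) @ U)
    Q = max(Q, 0.0)
    p = float(chi2.sf(Q, df=spec.h))
    res = TestResult(Q_lrt=Q, p_value=p, method="glm-rao", df=spec.h)
    res.converged = null.converged  # type: ignore[attr-defined]
    res.separated = null.separated  # type: ignore[attr-defined]
    return res
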
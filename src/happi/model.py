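"""Core probability model for quality-adjusted gene presence.

The hierarchical model: for genome ``i`` with covariates ``X_i`` and
quality variables ``M_i``, the latent presence indicator follows

    logit Pr(lambda_i = 1 | X_i) = X_i' beta,

and the observed detection indicator ``Y_i`` follows

    Pr(Y_i = 1 | lambda_i = 1, M_i) = f(M_i)      (detection curve)
    Pr(Y_i = 1 | lambda_i = 0, M_i) = epsilon     (contamination rate).

``f`` is monotone non-decreasing in genome quality and ``epsilon`` is a
fixed hyperparameter (``f`` and ``epsilon`` are not jointly identifiable).
Estimation is by EM with a Firth (Jeffreys-prior) penalty on ``beta``:

* E-step: posterior presence probabilities ``p_i`` by Bayes' rule;
* M-step for ``beta``: Firth-penalized logistic regression with the
  fractional outcomes ``p_i`` (Newton with step-halving);
* M-step for ``f``: weighted monotone logistic fit of ``Y`` on ``M`` with
  weights ``p_i``, either in the I-spline class (box-constrained Newton)
  or the bounded-isotonic class (pool-adjacent-violators with a
  ``-cosh((f~/a)^2)`` penalty keeping the logits bounded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import expit, logit

from .curves import DetectionCurve, ISplineCurve, IsotoneCurve, LinearCurve
from .splines import ISplineBasis

__all__ = [
    "HappiConfig",
    "ModelParameters",
    "PosteriorState",
    "eval_curve",
    "observed_loglik",
    "firth_penalty",
    "posterior_presence",
    "expected_penalized_loglik",
    "update_beta_firth",
    "update_f_ispline",
    "update_f_isotone",
    "update_f_linear",
    "fit_constant_curve",
]

_P_CLAMP = 1e-10  # posterior clamp for M-step stability


@dataclass
class HappiConfig:
    """Hyperparameters and fitting controls.

    Parameters
    ----------
    epsilon : float
        Probability of observing a gene in a genome where it is truly
        absent (contamination / crosstalk); fixed, never estimated.
    t_max : int
        Maximum number of EM iterations.
    delta : float
        Relative log-likelihood increase threshold for the stopping rule.
    min_iter : int
        Minimum EM iterations before convergence may be declared.
    consecutive_steps : int
        Number of consecutive sub-threshold steps required to stop.
    spline_df, spline_degree : int
        Number of I-spline basis functions and their degree.
    cosh_a : float
        Scale ``a`` of the ``-cosh((f~/a)^2)`` penalty in the isotonic fit.
    logit_cap : float
        Hard bound on the detection curve's logit values.
    f_class : str
        Detection-curve class: "ispline" (default), "isotone" or "linear".
    fix_curve : DetectionCurve, optional
        Freeze the detection curve at a user-supplied curve (skips the
        f update entirely).
    """

    epsilon: float = 0.0
    t_max: int = 1000
    delta: float = 0.01
    min_iter: int = 16
    consecutive_steps: int = 5
    spline_df: int = 4
    spline_degree: int = 3
    cosh_a: float = 50.0
    logit_cap: float = 10.0
    f_class: str = "ispline"
    fix_curve: DetectionCurve | None = None

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.t_max < self.min_iter:
            raise ValueError("t_max must be >= min_iter")
        if self.f_class not in ("ispline", "isotone", "linear"):
            raise ValueError(f"unknown f_class {self.f_class!r}")
        if self.cosh_a <= 0 or self.logit_cap <= 0:
            raise ValueError("cosh_a and logit_cap must be positive")


@dataclass
class ModelParameters:
    """theta = (beta, f): regression coefficients plus detection curve."""

    beta: np.ndarray
    curve: DetectionCurve

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")


@dataclass
class PosteriorState:
    """E-step output: posterior presence and log-likelihood values."""

    p: np.ndarray
    loglik: float
    penalized_loglik: float


def eval_curve(curve: DetectionCurve, M) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a detection curve: returns ``(f~ logits, f probabilities)``."""
    ftil = curve.eval_logit(M)
    return ftil, curve.eval_prob(M)


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _per_genome_prob(params: ModelParameters, Y, X, M, epsilon: float):
    """Marginal Pr(Y_i | theta) plus the two conditional pieces."""
    Y = np.asarray(Y, dtype=float).ravel()
    eta = np.asarray(X, dtype=float) @ params.beta
    pi = expit(eta)
    f = params.curve.eval_prob(M)
    lik_present = np.where(Y == 1, f, 1.0 - f)
    lik_absent = np.where(Y == 1, epsilon, 1.0 - epsilon)
    marginal = lik_present * pi + lik_absent * (1.0 - pi)
    return marginal, lik_present, lik_absent, pi


def observed_loglik(params: ModelParameters, Y, X, M, epsilon: float) -> float:
    """Observed-data log-likelihood, the latent indicator marginalised out.

    Returns ``-inf`` (with a warning naming the genome) if any datum has
    probability exactly zero, e.g. ``Y=1`` with ``epsilon=0`` and ``f=0``.
    """
    marginal, *_ = _per_genome_prob(params, Y, X, M, epsilon)
    if np.any(marginal <= 0.0):
        bad = int(np.argmax(marginal <= 0.0))
        warnings.warn(
            f"genome {bad} has zero probability under the current parameters",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf
    return float(np.sum(np.log(marginal)))


def firth_penalty(beta, X) -> float:
    """Jeffreys-prior penalty ``0.5 * log|X' W X|`` of the beta submodel."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return 0.0
    w = expit(X @ np.asarray(beta, dtype=float))
    wv = np.clip(w * (1.0 - w), 1e-12, None)
    sign, logdet = np.linalg.slogdet(X.T @ (X * wv[:, None]))
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "Fisher information is singular; check covariates for collinearity"
        )
    return 0.5 * logdet


def posterior_presence(params: ModelParameters, Y, X, M, epsilon: float,
                       clamp: bool = False) -> np.ndarray:
    """E-step: posterior probability that the gene is truly present.

    With ``epsilon = 0`` a detection cannot be contamination, so
    ``Y_i = 1`` forces ``p_i = 1`` exactly.  Set ``clamp=True`` to clip
    to ``[1e-10, 1 - 1e-10]`` for M-step stability.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    marginal, lik_present, _, pi = _per_genome_prob(params, Y, X, M, epsilon)
    if np.any(marginal <= 0.0):
        bad = int(np.argmax(marginal <= 0.0))
        raise ZeroDivisionError(
            f"posterior undefined for genome {bad}: marginal probability is zero"
        )
    p = lik_present * pi / marginal
    if epsilon == 0.0:
        p[Y == 1] = 1.0
    np.clip(p, 0.0, 1.0, out=p)
    if clamp:
        np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP, out=p)
    return p


def expected_penalized_loglik(beta, curve: DetectionCurve, epsilon: float,
                              p, Y, X, M) -> float:
    """Expected complete-data penalized log-likelihood given posteriors ``p``.

    Three weighted Bernoulli terms (detection given presence, detection
    given absence, presence given covariates) plus the Firth penalty.  The
    contamination term is constant in ``(beta, f)``; with ``epsilon = 0``
    it degenerates and is dropped (its weights ``(1-p_i) Y_i`` vanish).
    """
    p = np.asarray(p, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    ftil = curve.eval_logit(M)
    eta = X @ np.asarray(beta, dtype=float)
    term_f = float(np.sum(p * (Y * ftil - _log1pexp(ftil))))
    if epsilon == 0.0:
        term_eps = 0.0
    else:
        etil = logit(epsilon)
        term_eps = float(np.sum((1.0 - p) * (Y * etil - _log1pexp(etil))))
    term_beta = float(np.sum(p * eta - _log1pexp(eta)))
    return term_f + term_eps + term_beta + firth_penalty(beta, X)


# ---------------------------------------------------------------------------
# M-step 1: Firth-penalized logistic regression with fractional outcomes
# ---------------------------------------------------------------------------

def _firth_objective(beta, X, p, offset):
    eta = offset + X @ beta
    return float(np.sum(p * eta - _log1pexp(eta))) + firth_penalty_offset(beta, X, offset)


def firth_penalty_offset(beta, X, offset) -> float:
    if X.shape[1] == 0:
        return 0.0
    w = expit(offset + X @ beta)
    wv = np.clip(w * (1.0 - w), 1e-12, None)
    sign, logdet = np.linalg.slogdet(X.T @ (X * wv[:, None]))
    if sign <= 0:
        raise np.linalg.LinAlgError("singular Fisher information")
    return 0.5 * logdet


def update_beta_firth(X, p, offset=None, beta0=None, tol: float = 1e-8,
                      max_iter: int = 100, check_rank: bool = True):
    """Maximise the Firth-penalized weighted logistic log-likelihood.

    Newton scoring on the Firth-adjusted score with step-halving on the
    penalized objective.  Always returns a finite estimate (the Jeffreys
    penalty guarantees an interior maximiser even under separation).

    Returns
    -------
    beta : ndarray
    converged : bool
        Gradient 2-norm <= ``tol`` at return.
    """
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float).ravel()
    n, k = X.shape
    if k == 0:
        return np.zeros(0), True
    if check_rank and np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float).ravel()
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    obj = None
    best_beta, best_grad = beta.copy(), np.inf
    converged = False
    for _ in range(max_iter):
        w = expit(off + X @ beta)
        wv = np.clip(w * (1.0 - w), 1e-12, None)
        info = X.T @ (X * wv[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat diagonals of W^{1/2} X (X'WX)^{-1} X' W^{1/2}
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * wv
        score = X.T @ (p - w + h * (0.5 - w))
        gnorm = float(np.linalg.norm(score))
        if gnorm < best_grad:
            best_beta, best_grad = beta.copy(), gnorm
        if gnorm <= tol:
            converged = True
            break
        step = info_inv @ score
        if gnorm < 1e-6:
            # close enough that the safeguarded line search is unnecessary
            beta = beta + step
            continue
        if obj is None:
            obj = _firth_objective(beta, X, p, off)
        s = 1.0
        cand, cand_obj = beta + step, None
        for _half in range(40):
            cand = beta + s * step
            cand_obj = _firth_objective(cand, X, p, off)
            if cand_obj >= obj - 1e-12:
                break
            s *= 0.5
        beta, obj = cand, cand_obj
    if not converged:
        warnings.warn(
            f"Firth Newton did not reach gradient tolerance {tol:g} in "
            f"{max_iter} steps (best |grad| = {best_grad:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
        beta = best_beta
    return beta, converged


# ---------------------------------------------------------------------------
# M-step 2a: I-spline detection-curve update
# ---------------------------------------------------------------------------

def _weighted_logistic_obj(alpha, D, p, Y):
    eta = D @ alpha
    return float(np.sum(p * (Y * eta - _log1pexp(eta))))


def fit_constant_curve(p, Y, config: HappiConfig, basis: ISplineBasis) -> ISplineCurve:
    """Best constant detection curve: intercept-only weighted logistic fit."""
    p = np.asarray(p, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    total = float(np.sum(p))
    cap = config.logit_cap
    if total < 1e-8:
        a0 = 0.0
    else:
        mean = np.clip(np.sum(p * Y) / total, 1e-12, 1.0 - 1e-12)
        a0 = float(np.clip(logit(mean), -cap, cap))
    alpha = np.zeros(basis.n_basis + 1)
    alpha[0] = a0
    return ISplineCurve(basis=basis, alpha=alpha, logit_cap=config.logit_cap)


def _projected_newton(D, p, Y, x0, lower, upper, tol=1e-8, max_iter=40):
    """Box-constrained maximiser of the weighted Bernoulli log-likelihood."""
    alpha = np.clip(x0.copy(), lower, upper)
    obj = _weighted_logistic_obj(alpha, D, p, Y)
    for _ in range(max_iter):
        eta = D @ alpha
        mu = expit(eta)
        g = D.T @ (p * (Y - mu))
        at_lo = (alpha <= lower + 1e-12) & (g < 0)
        at_hi = (alpha >= upper - 1e-12) & (g > 0)
        gproj = g.copy()
        gproj[at_lo | at_hi] = 0.0
        gmax = float(np.max(np.abs(gproj), initial=0.0))
        if gmax <= tol:
            return alpha, obj, True
        free = ~(at_lo | at_hi)
        wv = np.clip(p * mu * (1.0 - mu), 1e-12, None)
        Df = D[:, free]
        H = Df.T @ (Df * wv[:, None]) + 1e-10 * np.eye(int(free.sum()))
        try:
            d_free = np.linalg.solve(H, g[free])
        except np.linalg.LinAlgError:
            d_free = g[free]
        s = 1.0
        improved = False
        for _half in range(30):
            cand = alpha.copy()
            cand[free] += s * d_free
            np.clip(cand, lower, upper, out=cand)
            cand_obj = _weighted_logistic_obj(cand, D, p, Y)
            if cand_obj >= obj + 1e-14 or (cand_obj >= obj and s < 1.0):
                alpha, obj = cand, cand_obj
                improved = True
                break
            s *= 0.5
        if not improved:
            # the objective can no longer be improved at float precision;
            # accept if the projected gradient is already small
            return alpha, obj, gmax <= 1e-5
    return alpha, obj, gmax <= 1e-5


def update_f_ispline(M, p, Y, config: HappiConfig,
                     basis: ISplineBasis | None = None,
                     warm: ISplineCurve | None = None) -> ISplineCurve:
    """Weighted monotone logistic fit of ``Y`` on an I-spline basis of ``M``.

    Maximises ``sum_i p_i [Y_i f~_i - log(1 + exp(f~_i))]`` over
    ``f~ = a0 + sum_j a_j I_j(M)`` with ``a_j >= 0``, subject to the fitted
    logits respecting the evaluation cap on the observed quality range
    (``a0 >= -logit_cap`` and ``a0 + sum_j a_j <= logit_cap``; the curve is
    monotone, so these endpoint constraints bound it everywhere).  Keeping
    the fit inside the cap makes the M-step objective identical to the
    capped likelihood the EM monitors, preserving monotone ascent.  Falls
    back to the constant fit if the constrained optimiser fails to improve
    on it.
    """
    M = np.asarray(M, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    if basis is None:
        basis = ISplineBasis.from_data(M, config.spline_df, config.spline_degree)
    const = fit_constant_curve(p, Y, config, basis)
    if np.sum(p) < 1e-8:
        return const
    D = np.column_stack([np.ones(M.size), basis.design(M)])
    k = basis.n_basis
    cap = config.logit_cap
    lower = np.r_[-cap, np.zeros(k)]
    upper = np.r_[cap, np.full(k, 2.0 * cap)]
    x0 = const.alpha.copy()
    if warm is not None and warm.alpha is not None and warm.alpha.size == k + 1:
        if _weighted_logistic_obj(np.clip(warm.alpha, lower, upper), D, p, Y) > \
           _weighted_logistic_obj(x0, D, p, Y):
            x0 = np.clip(warm.alpha, lower, upper)
    alpha, obj, ok = _projected_newton(D, p, Y, x0, lower, upper)
    if not ok:
        res = minimize(
            lambda a: -_weighted_logistic_obj(a, D, p, Y),
            alpha,
            jac=lambda a: -(D.T @ (p * (Y - expit(D @ a)))),
            method="L-BFGS-B",
            bounds=list(zip(lower, upper)),
        )
        if res.fun is not None and -res.fun > obj:
            alpha, obj = res.x, -res.fun
    if alpha[0] + np.sum(alpha[1:]) > cap + 1e-9:
        # upper endpoint exceeds the cap: redo with the endpoint constraint
        from scipy.optimize import LinearConstraint

        A = np.r_[1.0, np.ones(k)]
        res = minimize(
            lambda a: -_weighted_logistic_obj(a, D, p, Y),
            np.clip(x0, lower, upper),
            jac=lambda a: -(D.T @ (p * (Y - expit(D @ a)))),
            method="SLSQP",
            bounds=list(zip(lower, upper)),
            constraints=[LinearConstraint(A, -np.inf, cap)],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if res.x is not None:
            cand = np.asarray(res.x, dtype=float)
            cand[1:] = np.maximum(cand[1:], 0.0)
            excess = cand[0] + cand[1:].sum() - cap
            if excess > 0:  # tolerance round-off: shave the intercept
                cand[0] -= excess
            alpha, obj = cand, _weighted_logistic_obj(cand, D, p, Y)
    const_obj = _weighted_logistic_obj(const.alpha, D, p, Y)
    if obj < const_obj - 1e-12:
        warnings.warn("I-spline update failed to beat the constant fit; "
                      "falling back to the constant curve", RuntimeWarning,
                      stacklevel=2)
        return const
    alpha = np.asarray(alpha, dtype=float)
    alpha[1:] = np.maximum(alpha[1:], 0.0)
    return ISplineCurve(basis=basis, alpha=alpha, logit_cap=config.logit_cap)


def update_f_linear(M, p, Y, config: HappiConfig,
                    warm: LinearCurve | None = None) -> LinearCurve:
    """Logit-linear curve update with non-negative slopes (any q >= 1)."""
    M2 = np.asarray(M, dtype=float)
    if M2.ndim == 1:
        M2 = M2[:, None]
    p = np.asarray(p, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    D = np.column_stack([np.ones(M2.shape[0]), M2])
    q = M2.shape[1]
    cap = 2.0 * config.logit_cap
    scale = np.maximum(np.abs(M2).max(axis=0), 1e-8)
    lower = np.r_[-cap, np.zeros(q)]
    upper = np.r_[cap, 4.0 * config.logit_cap / scale]
    x0 = np.zeros(q + 1)
    if np.sum(p) >= 1e-8:
        mean = np.clip(np.sum(p * Y) / np.sum(p), 1e-12, 1 - 1e-12)
        x0[0] = np.clip(logit(mean), -cap, cap)
    if warm is not None and warm.slopes is not None:
        x0 = np.clip(np.r_[warm.intercept, warm.slopes], lower, upper)
    alpha, _, _ = _projected_newton(D, p, Y, x0, lower, upper)
    return LinearCurve(intercept=float(alpha[0]),
                       slopes=np.maximum(alpha[1:], 0.0),
                       logit_cap=config.logit_cap)


# ---------------------------------------------------------------------------
# M-step 2b: bounded isotonic detection-curve update
# ---------------------------------------------------------------------------

def _block_solve(sp, spy, nb, a, bound):
    """Root of the pooled penalized score
    ``spy - sp*expit(v) - nb * sinh((v/a)^2) * 2v/a^2 = 0`` (decreasing in v).
    """
    def score(v):
        return spy - sp * expit(v) - nb * np.sinh((v / a) ** 2) * 2.0 * v / a**2

    lo, hi = -bound, bound
    if score(lo) <= 0.0:
        return lo
    if score(hi) >= 0.0:
        return hi
    return brentq(score, lo, hi, xtol=1e-10)


def update_f_isotone(M, p, Y, config: HappiConfig) -> IsotoneCurve:
    """Isotonic detection-curve update with a cosh penalty on the logits.

    Pool-adjacent-violators over the per-observation convex loss
    ``-p_i [Y_i v - log(1+exp(v))] + cosh((v/a)^2)``, subject to ``v``
    non-decreasing in ``M``; ties in ``M`` share a fitted value.
    """
    M = np.asarray(M, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    a = config.cosh_a
    # the cosh penalty dominates the (bounded) likelihood score well before
    # this bracket, so block roots always lie inside it
    bound = max(6.0 * config.logit_cap, 4.0 * a)

    bp = np.unique(M)
    sp = np.zeros(bp.size)
    spy = np.zeros(bp.size)
    nb = np.zeros(bp.size)
    idx = np.searchsorted(bp, M)
    np.add.at(sp, idx, p)
    np.add.at(spy, idx, p * Y)
    np.add.at(nb, idx, 1.0)

    # PAVA with general convex per-block losses: each block's value is the
    # root of its pooled score; merge while monotonicity is violated
    blocks: list[list[float]] = []  # [sp, spy, nb, value, count_of_bp]
    for j in range(bp.size):
        blocks.append([sp[j], spy[j], nb[j],
                       _block_solve(sp[j], spy[j], nb[j], a, bound), 1])
        while len(blocks) > 1 and blocks[-2][3] >= blocks[-1][3] - 1e-12:
            s2, y2, n2, _, c2 = blocks.pop()
            s1, y1, n1, _, c1 = blocks.pop()
            merged = [s1 + s2, y1 + y2, n1 + n2, 0.0, c1 + c2]
            merged[3] = _block_solve(merged[0], merged[1], merged[2], a, bound)
            blocks.append(merged)
    values = np.concatenate([np.full(int(b[4]), b[3]) for b in blocks])
    # enforce exact monotonicity against root-finder round-off
    values = np.maximum.accumulate(values)
    return IsotoneCurve(breakpoints=bp, values=values, logit_cap=config.logit_cap)
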
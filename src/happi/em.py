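"""EM fitting and hypothesis testing.

Fits the quality-adjusted presence model by EM (full and null-constrained),
tests linear hypotheses ``A beta = c`` by likelihood-ratio — either against
the asymptotic chi-square reference or by permutation — and adjusts
per-gene p-values for multiple testing by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .curves import DetectionCurve, ISplineCurve
from .model import (
    HappiConfig,
    ModelParameters,
    PosteriorState,
    fit_constant_curve,
    firth_penalty_offset,
    observed_loglik,
    posterior_presence,
    update_beta_firth,
    update_f_isotone,
    update_f_ispline,
    update_f_linear,
)
from .splines import ISplineBasis

__all__ = [
    "FitResult",
    "TestSpec",
    "TestResult",
    "PermutationConfig",
    "fit_happi",
    "fit_null",
    "lrt_asymptotic",
    "lrt_permutation",
    "test_gene",
    "bh_adjust",
    "epsilon_sensitivity",
]


@dataclass
class FitResult:
    """A converged (or capped) EM fit."""

    params: ModelParameters
    posterior: PosteriorState
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    flags: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        """Unpenalized observed-data log-likelihood at the estimate."""
        return self.posterior.loglik

    @property
    def penalized_loglik(self) -> float:
        return self.posterior.penalized_loglik


@dataclass
class TestSpec:
    """Linear hypothesis ``A beta = c`` with ``rank(A) = h``."""

    __test__ = False  # not a pytest class, despite the name

    A: np.ndarray
    c: np.ndarray
    tested: tuple[int, ...] | None = None  # covariate columns being tested

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.c = np.asarray(self.c, dtype=float).ravel()
        if self.A.shape[0] != self.c.size:
            raise ValueError("A and c have incompatible shapes")
        if np.linalg.matrix_rank(self.A) != self.A.shape[0]:
            raise ValueError("constraint matrix A must have full row rank")
        if self.A.shape[0] > self.A.shape[1]:
            raise ValueError("cannot have more constraints than coefficients")

    @property
    def h(self) -> int:
        return self.A.shape[0]

    @classmethod
    def coefficients(cls, indices, p: int, values=0.0) -> "TestSpec":
        """Test ``beta_k = value`` for each coefficient index ``k``."""
        indices = tuple(int(i) for i in np.atleast_1d(indices))
        values = np.broadcast_to(np.asarray(values, dtype=float), (len(indices),))
        A = np.zeros((len(indices), p))
        for row, k in enumerate(indices):
            A[row, k] = 1.0
        return cls(A=A, c=values.copy(), tested=indices)


@dataclass
class TestResult:
    """Outcome of a likelihood-ratio test for one gene."""

    __test__ = False  # not a pytest class, despite the name

    Q_lrt: float
    p_value: float
    method: str
    df: int
    B_used: int | None = None
    fit_alt: FitResult | None = None
    fit_null: FitResult | None = None


@dataclass
class PermutationConfig:
    B: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.B < 19:
            raise ValueError("need at least B=19 permutations to resolve alpha=0.05")


def _initial_params(Y, X, M, config: HappiConfig,
                    basis: ISplineBasis | None) -> ModelParameters:
    Y = np.asarray(Y, dtype=float).ravel()
    p = np.clip(Y, 1e-10, 1 - 1e-10)
    if config.fix_curve is not None:
        curve: DetectionCurve = config.fix_curve
    elif config.f_class == "ispline":
        curve = fit_constant_curve(np.ones_like(Y), Y, config, basis)
    elif config.f_class == "linear":
        curve = update_f_linear(M, np.ones_like(Y), Y, config)
    else:
        curve = update_f_isotone(M, np.ones_like(Y), Y, config)
    beta = np.zeros(np.asarray(X).shape[1])
    return ModelParameters(beta=beta, curve=curve)


def fit_happi(Y_gene, X, M, config: HappiConfig | None = None,
              constraint: TestSpec | None = None,
              init: ModelParameters | None = None) -> FitResult:
    """Fit the model by EM; optionally under the constraint ``A beta = c``.

    The constrained fit reparameterises ``beta = beta0 + N gamma`` with
    ``A beta0 = c`` (least-squares particular solution) and ``N`` a basis
    of the null space of ``A``; the Firth penalty is computed on the
    reduced design ``X N``.  The stopping rule: at most ``t_max``
    iterations, or stop once the relative increase of the penalized
    observed-data log-likelihood has been below ``delta`` for
    ``consecutive_steps`` consecutive iterations (after ``min_iter``).
    """
    config = config or HappiConfig()
    Y = np.asarray(Y_gene, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    n = Y.size
    if X.shape[0] != n or M.shape[0] != n:
        raise ValueError("Y, X and M must be aligned on genomes")
    if not np.all(np.isin(Y, (0.0, 1.0))):
        raise ValueError("Y must be binary")
    p_cov = X.shape[1]

    if constraint is not None:
        if constraint.A.shape[1] != p_cov:
            raise ValueError("constraint width does not match the design")
        beta0, *_ = np.linalg.lstsq(constraint.A, constraint.c, rcond=None)
        N = null_space(constraint.A)
        X_red = X @ N
        offset = X @ beta0
    else:
        beta0 = np.zeros(p_cov)
        N = np.eye(p_cov)
        X_red = X
        offset = np.zeros(n)

    if X_red.shape[1] and np.linalg.matrix_rank(X_red) < X_red.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    basis = None
    if config.f_class == "ispline" and config.fix_curve is None:
        basis = ISplineBasis.from_data(M, config.spline_df, config.spline_degree)

    params = init if init is not None else _initial_params(Y, X, M, config, basis)
    if init is not None and config.f_class == "ispline" and config.fix_curve is None:
        if isinstance(init.curve, ISplineCurve):
            basis = init.curve.basis

    flags = {}
    if config.epsilon == 0.0 and (np.all(Y == 0) or np.all(Y == 1)):
        flags["non_identified"] = True

    gamma = np.linalg.lstsq(N, params.beta - beta0, rcond=None)[0] if N.size else np.zeros(0)

    def penalized(par: ModelParameters, g) -> tuple[float, float]:
        ll = observed_loglik(par, Y, X, M, config.epsilon)
        return ll, ll + firth_penalty_offset(g, X_red, offset)

    trace = []
    prev = None
    streak = 0
    converged = False
    n_iter = 0
    p_post = posterior_presence(params, Y, X, M, config.epsilon)
    for t in range(1, config.t_max + 1):
        n_iter = t
        p_work = np.clip(p_post, 1e-10, 1 - 1e-10)
        # M-step, beta block
        if X_red.shape[1] > 0:
            gamma, _ = update_beta_firth(X_red, p_work, offset=offset,
                                         beta0=gamma, check_rank=False)
            beta = beta0 + N @ gamma
        else:
            beta = beta0
        # M-step, detection-curve block
        if config.fix_curve is not None:
            curve = config.fix_curve
        elif config.f_class == "ispline":
            warm = params.curve if isinstance(params.curve, ISplineCurve) else None
            curve = update_f_ispline(M, p_work, Y, config, basis=basis, warm=warm)
        elif config.f_class == "linear":
            curve = update_f_linear(M, p_work, Y, config)
        else:
            curve = update_f_isotone(M, p_work, Y, config)
        params = ModelParameters(beta=beta, curve=curve)
        # E-step for the next iteration + convergence monitor
        p_post = posterior_presence(params, Y, X, M, config.epsilon)
        ll, pen_ll = penalized(params, gamma)
        trace.append(pen_ll)
        if prev is not None:
            rel = (pen_ll - prev) / (abs(prev) + 1e-12)
            streak = streak + 1 if rel < config.delta else 0
            if streak >= config.consecutive_steps and t >= config.min_iter:
                converged = True
                break
        prev = pen_ll

    ll = observed_loglik(params, Y, X, M, config.epsilon)
    pen_ll = ll + firth_penalty_offset(gamma, X_red, offset)
    posterior = PosteriorState(p=p_post, loglik=ll, penalized_loglik=pen_ll)
    return FitResult(params=params, posterior=posterior,
                     loglik_trace=np.asarray(trace), n_iter=n_iter,
                     converged=converged, flags=flags)


def fit_null(Y_gene, X, M, config: HappiConfig, spec: TestSpec,
             init: ModelParameters | None = None) -> FitResult:
    """Maximum likelihood under the null hypothesis ``A beta = c``."""
    return fit_happi(Y_gene, X, M, config, constraint=spec, init=init)


def _fit_pair(Y, X, M, config, spec, init_alt=None, init_null=None):
    alt = fit_happi(Y, X, M, config, init=init_alt)
    null = fit_happi(Y, X, M, config, constraint=spec, init=init_null)
    if null.loglik > alt.loglik + 1e-6:
        # The null optimum is feasible for the alternative: warm-restart.
        # Small residual violations remain possible because estimation
        # maximises the *penalized* likelihood and the alternative and
        # null carry different Firth penalties (full vs reduced design);
        # such Q values are floored at zero by the tests.
        alt2 = fit_happi(Y, X, M, config, init=null.params)
        if alt2.loglik >= alt.loglik:
            alt = alt2
        if null.loglik > alt.loglik + 2.0:
            raise RuntimeError(
                "null log-likelihood exceeds the alternative after warm restart; "
                "EM failed to maximise the observed-data likelihood"
            )
    return alt, null


def lrt_asymptotic(alt: FitResult, null: FitResult, h: int) -> TestResult:
    """Likelihood-ratio test against the chi-square(h) reference.

    The statistic uses the unpenalized observed-data log-likelihood; the
    Firth penalty is an estimation device only.  ``Q`` is floored at zero
    (nesting makes negative values numerical noise).
    """
    Q = 2.0 * (alt.loglik - null.loglik)
    if Q < -0.2:
        warnings.warn(f"negative LRT statistic {Q:.3g} floored at 0",
                      RuntimeWarning, stacklevel=2)
    Q = max(Q, 0.0)
    p = float(chi2.sf(Q, df=h))
    return TestResult(Q_lrt=Q, p_value=p, method="asymptotic", df=h,
                      fit_alt=alt, fit_null=null)


def lrt_permutation(Y_gene, X, M, config: HappiConfig, spec: TestSpec,
                    perm: PermutationConfig) -> TestResult:
    """Permutation reference distribution for the LRT statistic.

    The tested covariate columns of ``X`` are permuted jointly across
    genomes (holding ``Y``, ``M`` and untested columns fixed) and the
    statistic recomputed for each of ``B`` permutations; the p-value is
    the add-one estimator ``(1 + #{Q_b >= Q_0}) / (B + 1)``.  Null and
    alternative refits are warm-started from the observed fits.
    """
    if spec.tested is None:
        raise ValueError("permutation testing requires TestSpec.tested "
                         "(the covariate columns to permute)")
    X = np.asarray(X, dtype=float)
    alt, null = _fit_pair(Y_gene, X, M, config, spec)
    Q0 = max(2.0 * (alt.loglik - null.loglik), 0.0)
    rng = np.random.default_rng(perm.seed)
    cols = list(spec.tested)
    count = 0
    for _ in range(perm.B):
        order = rng.permutation(X.shape[0])
        Xb = X.copy()
        Xb[:, cols] = X[order][:, cols]
        alt_b, null_b = _fit_pair(Y_gene, Xb, M, config, spec,
                                  init_alt=alt.params, init_null=null.params)
        Qb = max(2.0 * (alt_b.loglik - null_b.loglik), 0.0)
        if Qb >= Q0:
            count += 1
    p = (1.0 + count) / (perm.B + 1.0)
    return TestResult(Q_lrt=Q0, p_value=p, method="permutation", df=spec.h,
                      B_used=perm.B, fit_alt=alt, fit_null=null)


def test_gene(Y_gene, X, M, config: HappiConfig, spec: TestSpec,
              method: str = "asymptotic",
              perm: PermutationConfig | None = None) -> TestResult:
    """Run one quality-adjusted presence test for a single gene."""
    if method == "asymptotic":
        alt, null = _fit_pair(Y_gene, X, M, config, spec)
        return lrt_asymptotic(alt, null, spec.h)
    if method == "permutation":
        if perm is None:
            raise ValueError("permutation testing requires a PermutationConfig")
        return lrt_permutation(Y_gene, X, M, config, spec, perm)
    raise ValueError(f"unknown method {method!r}")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def epsilon_sensitivity(Y_gene, X, M, config: HappiConfig, spec: TestSpec,
                        eps_grid, method: str = "asymptotic",
                        perm: PermutationConfig | None = None) -> pd.DataFrame:
    """Re-run the test across a grid of contamination rates ``epsilon``.

    A result robust across plausible epsilon values does not hinge on the
    assumption of negligible contamination.  Duplicate grid entries are
    dropped with a warning; rows are ordered by epsilon.
    """
    grid = np.asarray(list(eps_grid), dtype=float)
    uniq = np.unique(grid)
    if uniq.size < grid.size:
        warnings.warn("duplicate epsilon values in grid were removed",
                      UserWarning, stacklevel=2)
    rows = []
    for eps in uniq:
        cfg = HappiConfig(**{**config.__dict__, "epsilon": float(eps)})
        res = test_gene(Y_gene, X, M, cfg, spec, method=method, perm=perm)
        rows.append({"epsilon": float(eps), "Q_lrt": res.Q_lrt,
                     "p_value": res.p_value})
    return pd.DataFrame(rows)
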
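"""Synthetic data generation and error-rate / power study harnesses.

The generator draws data from the hierarchical presence model itself:
coverage runs over a deterministic grid ``M_i = 10 + 30 (i-1)/(n-1)``, the
covariate of interest is Gaussian with mean ``(i-1)/(n-1)`` and standard
deviation ``sigma_x`` (smaller ``sigma_x`` means stronger correlation
between coverage and the covariate — the regime where quality-naive tests
break down), presence is Bernoulli with logit ``X beta``, and detection of
a present gene follows a monotone coverage -> detection curve.

The default detection curve is the logit-linear surrogate
``f(m) = expit(-2 + 0.3 m)``: near 0.12 at zero coverage, about 0.73 at
the grid's lowest coverage (10x), and essentially 1 beyond 30x — a rising
curve of the shape seen in read-subsampling experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .baselines import glm_lrt, glm_rao
from .em import (
    HappiConfig,
    TestSpec,
    _fit_pair,
    lrt_asymptotic,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "surrogate_detection_curve",
    "simulate_dataset",
    "run_type1_study",
    "run_power_study",
    "compare_f_estimators",
]


def surrogate_detection_curve(m) -> np.ndarray:
    """Monotone coverage -> detection probability, ``expit(-2 + 0.3 m)``."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("coverage must be non-negative")
    return expit(np.clip(-2.0 + 0.3 * m, -10.0, 10.0))


@dataclass
class SimulationConfig:
    """One cell of the simulation design."""

    n: int = 100
    beta: tuple[float, float] = (0.0, 0.0)
    sigma_x: float = 0.5
    epsilon: float = 0.0
    curve: Callable[[np.ndarray], np.ndarray] = surrogate_detection_curve
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("need at least 4 genomes")
        if self.sigma_x <= 0:
            raise ValueError("sigma_x must be positive")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must lie in [0, 1)")


@dataclass
class SimulatedDataset:
    Y: np.ndarray
    X: np.ndarray
    M: np.ndarray
    lam: np.ndarray  # true latent presence
    config: SimulationConfig = field(repr=False)


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw one dataset from the generative model.

    Draw order is fixed (covariate, then presence, then detection) so a
    given seed reproduces the dataset bit-for-bit.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n
    i = np.arange(n, dtype=float)
    M = 10.0 + 30.0 * i / (n - 1)
    x2 = rng.normal(loc=i / (n - 1), scale=config.sigma_x)
    X = np.column_stack([np.ones(n), x2])
    beta = np.asarray(config.beta, dtype=float)
    lam = rng.binomial(1, expit(X @ beta)).astype(float)
    f = np.asarray(config.curve(M), dtype=float)
    detect_prob = np.where(lam == 1, f, config.epsilon)
    Y = rng.binomial(1, detect_prob).astype(float)
    return SimulatedDataset(Y=Y, X=X, M=M, lam=lam, config=config)


def _wald_ci(k: int, n: int, level: float = 0.95):
    from scipy.stats import norm

    rate = k / n
    z = float(norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(max(rate * (1.0 - rate), 0.0) / n)
    return max(rate - half, 0.0), min(rate + half, 1.0)


def _sim_pvalues(data: SimulatedDataset, methods: Sequence[str],
                 config: HappiConfig, B: int, perm_seed: int) -> dict[str, float]:
    spec = TestSpec.coefficients([1], p=2)
    out: dict[str, float] = {}
    need_happi = any(m.startswith("happi") for m in methods)
    if need_happi:
        alt, null = _fit_pair(data.Y, data.X, data.M, config, spec)
        Q0 = max(2.0 * (alt.loglik - null.loglik), 0.0)
        if "happi-a" in methods:
            out["happi-a"] = lrt_asymptotic(alt, null, spec.h).p_value
        if "happi-np" in methods:
            rng = np.random.default_rng(perm_seed)
            count = 0
            for _ in range(B):
                order = rng.permutation(data.X.shape[0])
                Xb = data.X.copy()
                Xb[:, 1] = data.X[order, 1]
                alt_b, null_b = _fit_pair(data.Y, Xb, data.M, config, spec,
                                          init_alt=alt.params,
                                          init_null=null.params)
                if max(2.0 * (alt_b.loglik - null_b.loglik), 0.0) >= Q0:
                    count += 1
            out["happi-np"] = (1.0 + count) / (B + 1.0)
    if "glm-lrt" in methods:
        out["glm-lrt"] = glm_lrt(data.Y, data.X, spec).p_value
    if "glm-rao" in methods:
        out["glm-rao"] = glm_rao(data.Y, data.X, spec).p_value
    return out


def _run_study(cells, methods, n_sim, B, alpha, seed, happi_config):
    """Shared driver: per cell, per replicate, one dataset scored by all
    requested methods on the same draw."""
    base = happi_config or HappiConfig(epsilon=0.0, t_max=1000, delta=0.1,
                                       min_iter=16)
    root = np.random.SeedSequence(seed)
    rows = []
    for cell_idx, (n, sigma_x, beta1) in enumerate(cells):
        rejections = {m: 0 for m in methods}
        for rep in range(n_sim):
            rep_ss = np.random.SeedSequence(entropy=root.entropy,
                                            spawn_key=(cell_idx, rep))
            rng = np.random.default_rng(rep_ss)
            perm_seed = int(rng.integers(2**31))
            cfg = SimulationConfig(n=n, beta=(0.0, beta1), sigma_x=sigma_x,
                                   epsilon=base.epsilon, seed=0)
            data = simulate_dataset(cfg, rng=rng)
            pvals = _sim_pvalues(data, methods, base, B, perm_seed)
            for m, pv in pvals.items():
                if pv < alpha:
                    rejections[m] += 1
        for m in methods:
            lo, hi = _wald_ci(rejections[m], n_sim)
            rows.append({"n": n, "sigma_x": sigma_x, "beta1": beta1,
                         "method": m, "n_sim": n_sim, "alpha": alpha,
                         "n_reject": rejections[m],
                         "rate": rejections[m] / n_sim,
                         "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


def run_type1_study(ns: Sequence[int] = (30, 50, 100),
                    sigma_xs: Sequence[float] = (0.25, 0.5),
                    methods: Sequence[str] = ("happi-a", "happi-np",
                                              "glm-lrt", "glm-rao"),
                    n_sim: int = 500, B: int = 1000, alpha: float = 0.05,
                    seed: int = 0,
                    happi_config: HappiConfig | None = None) -> pd.DataFrame:
    """Empirical type-1 error rates under the null (``beta1 = 0``).

    Returns one row per (n, sigma_x, method) with the rejection rate and a
    95% Wald binomial confidence interval.
    """
    cells = [(n, sx, 0.0) for n in ns for sx in sigma_xs]
    return _run_study(cells, list(methods), n_sim, B, alpha, seed, happi_config)


def run_power_study(ns: Sequence[int] = (30, 50, 100),
                    sigma_xs: Sequence[float] = (0.25, 0.5),
                    beta1s: Sequence[float] = (0.5, 1.0, 2.0),
                    methods: Sequence[str] = ("happi-a", "happi-np"),
                    n_sim: int = 500, B: int = 1000, alpha: float = 0.05,
                    seed: int = 0,
                    happi_config: HappiConfig | None = None) -> pd.DataFrame:
    """Empirical power under ``beta = (0, beta1)`` with ``beta1 != 0``.

    With ``beta1 = 0`` this reduces exactly to the type-1 harness.
    """
    cells = [(n, sx, b1) for n in ns for sx in sigma_xs for b1 in beta1s]
    return _run_study(cells, list(methods), n_sim, B, alpha, seed, happi_config)


def compare_f_estimators(ns: Sequence[int] = (30, 50, 100),
                         beta1s: Sequence[float] = (0.5, 1.0, 2.0),
                         sigma_xs: Sequence[float] = (0.25, 0.5),
                         n_rep: int = 250, seed: int = 0,
                         happi_config: HappiConfig | None = None) -> pd.DataFrame:
    """Compare the two detection-curve classes as estimators of ``beta1``.

    For each (n, beta1, sigma_x) cell, fits the model with the I-spline
    curve and with the bounded-isotonic curve on the same draws; one row
    per cell with mean and median squared error of ``beta1`` under both
    classes and a flag for which class wins on MSE.
    """
    base = happi_config or HappiConfig(epsilon=0.0, t_max=1000, delta=0.1,
                                       min_iter=16)
    root = np.random.SeedSequence(seed)
    rows = []
    cells = [(n, b1, sx) for n in ns for b1 in beta1s for sx in sigma_xs]
    for cell_idx, (n, beta1, sigma_x) in enumerate(cells):
        est = {"ispline": [], "isotone": []}
        for rep in range(n_rep):
            rep_ss = np.random.SeedSequence(entropy=root.entropy,
                                            spawn_key=(cell_idx, rep))
            rng = np.random.default_rng(rep_ss)
            cfg = SimulationConfig(n=n, beta=(0.0, beta1), sigma_x=sigma_x,
                                   epsilon=base.epsilon, seed=0)
            data = simulate_dataset(cfg, rng=rng)
            for f_class in ("ispline", "isotone"):
                cfg_f = HappiConfig(**{**base.__dict__, "f_class": f_class})
                from .em import fit_happi

                fit = fit_happi(data.Y, data.X, data.M, cfg_f)
                est[f_class].append(fit.params.beta[1])
        row = {"n": n, "beta1": beta1, "sigma_x": sigma_x, "n_rep": n_rep}
        for f_class in ("ispline", "isotone"):
            err = (np.asarray(est[f_class]) - beta1) ** 2
            row[f"mse_{f_class}"] = float(err.mean())
            row[f"median_se_{f_class}"] = float(np.median(err))
        row["ispline_wins_mse"] = row["mse_ispline"] <= row["mse_isotone"]
        rows.append(row)
    return pd.DataFrame(rows)
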
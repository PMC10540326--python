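"""Detection-curve representations.

The detection curve ``f`` maps a genome-quality variable (e.g. mean
coverage, completion) to the probability of observing a gene that is truly
present.  All fitted representations are monotone non-decreasing:

* :class:`ISplineCurve` — intercept plus a non-negative combination of
  I-spline basis functions (the default class);
* :class:`IsotoneCurve` — a non-decreasing step function on the observed
  quality values (isotonic regression with a bespoke loss);
* :class:`LinearCurve` — logit-linear in the quality variables with
  non-negative slopes, the only representation supported for q >= 2;
* :class:`FixedCurve` — a constant detection probability, held fixed (used
  for degenerate fits and for freezing the curve in reductions to plain
  logistic regression).

Curves evaluate on the logit scale (``eval_logit``, clipped to
``+/- logit_cap``) and on the probability scale (``eval_prob``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .splines import ISplineBasis

__all__ = ["DetectionCurve", "ISplineCurve", "IsotoneCurve", "LinearCurve", "FixedCurve"]


class CurveStateError(RuntimeError):
    """Raised when an unfitted curve is evaluated."""


class DetectionCurve:
    """Abstract monotone detection curve."""

    f_class: str = "abstract"
    logit_cap: float = 10.0

    def eval_logit(self, m) -> np.ndarray:
        raise NotImplementedError

    def eval_prob(self, m) -> np.ndarray:
        return expit(self.eval_logit(m))

    def __call__(self, m) -> np.ndarray:
        return self.eval_prob(m)


@dataclass
class ISplineCurve(DetectionCurve):
    """Intercept + non-negative I-spline combination on the logit scale."""

    basis: ISplineBasis
    alpha: np.ndarray | None = None  # (1 + n_basis,): [intercept, coefs >= 0]
    logit_cap: float = 10.0
    f_class: str = field(default="ispline", init=False)

    def coefficients(self) -> np.ndarray:
        if self.alpha is None:
            raise CurveStateError("I-spline curve has not been fitted")
        return np.asarray(self.alpha, dtype=float)

    def eval_logit(self, m) -> np.ndarray:
        a = self.coefficients()
        if np.any(a[1:] < -1e-12):
            raise ValueError("I-spline basis coefficients must be non-negative")
        eta = a[0] + self.basis.design(m) @ a[1:]
        return np.clip(eta, -self.logit_cap, self.logit_cap)


@dataclass
class IsotoneCurve(DetectionCurve):
    """Non-decreasing step function over observed quality values.

    ``values`` holds fitted logits at the sorted distinct ``breakpoints``;
    evaluation is left-step with constant extrapolation outside the range.
    """

    breakpoints: np.ndarray | None = None
    values: np.ndarray | None = None
    logit_cap: float = 10.0
    f_class: str = field(default="isotone", init=False)

    def eval_logit(self, m) -> np.ndarray:
        if self.breakpoints is None or self.values is None:
            raise CurveStateError("isotone curve has not been fitted")
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if np.any(np.diff(vals) < -1e-9):
            raise ValueError("isotone curve values must be non-decreasing")
        m = np.asarray(m, dtype=float).ravel()
        idx = np.clip(np.searchsorted(bp, m, side="right") - 1, 0, bp.size - 1)
        return np.clip(vals[idx], -self.logit_cap, self.logit_cap)


@dataclass
class LinearCurve(DetectionCurve):
    """Logit-linear curve ``f~(M) = a0 + M @ w`` with slopes ``w >= 0``.

    The only representation available for multivariate quality (q >= 2);
    monotone non-decreasing in every quality coordinate.
    """

    intercept: float = 0.0
    slopes: np.ndarray | None = None
    logit_cap: float = 10.0
    f_class: str = field(default="linear", init=False)

    def eval_logit(self, m) -> np.ndarray:
        if self.slopes is None:
            raise CurveStateError("linear curve has not been fitted")
        w = np.asarray(self.slopes, dtype=float)
        if np.any(w < -1e-12):
            raise ValueError("linear curve slopes must be non-negative")
        m = np.asarray(m, dtype=float)
        if m.ndim == 1:
            m = m[:, None]
        eta = self.intercept + m @ w
        return np.clip(eta, -self.logit_cap, self.logit_cap)


@dataclass
class FixedCurve(DetectionCurve):
    """Constant detection probability, never updated by the EM.

    ``prob`` may be exactly 0 or 1, which the capped-logit representations
    cannot express; ``eval_prob`` therefore returns ``prob`` exactly while
    ``eval_logit`` returns the capped logit.
    """

    prob: float = 0.5
    logit_cap: float = 10.0
    f_class: str = field(default="fixed", init=False)

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("fixed detection probability must be in [0, 1]")

    def eval_logit(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        n = m.shape[0] if m.ndim else 1
        with np.errstate(divide="ignore"):
            lv = logit(self.prob)
        return np.full(n, np.clip(lv, -self.logit_cap, self.logit_cap))

    def eval_prob(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        n = m.shape[0] if m.ndim else 1
        return np.full(n, self.prob)
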
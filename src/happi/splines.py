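"""Monotone I-spline basis functions.

An I-spline of degree *d* is the running integral of the corresponding
M-spline (a B-spline normalised to integrate to one).  Every I-spline is
non-decreasing and rises from 0 at the lower boundary knot to 1 at the
upper boundary knot, so any non-negative combination of I-splines (plus a
free intercept) is a non-decreasing function — the property the detection
curve relies on.

The basis is built directly from :class:`scipy.interpolate.BSpline`
antiderivatives, so evaluation is exact (piecewise polynomial), not a
quadrature approximation.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["ISplineBasis"]


class ISplineBasis:
    """I-spline basis on a bounded interval.

    Parameters
    ----------
    boundary : (float, float)
        Lower and upper boundary knots ``(a, b)`` with ``a < b``.
    interior : sequence of float
        Interior knots, strictly inside ``(a, b)``.
    degree : int
        Degree of the underlying M-splines (default 3, cubic).

    Notes
    -----
    The number of basis functions is ``len(interior) + degree + 1``.
    Inputs outside ``[a, b]`` are evaluated at the nearest boundary
    (constant extrapolation), which preserves monotonicity and bounds.
    """

    def __init__(self, boundary, interior=(), degree: int = 3):
        a, b = float(boundary[0]), float(boundary[1])
        if not np.isfinite(a) or not np.isfinite(b) or not b > a:
            raise ValueError(f"boundary knots must satisfy a < b, got ({a}, {b})")
        interior = np.sort(np.asarray(interior, dtype=float))
        if interior.size and (interior[0] <= a or interior[-1] >= b):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if degree < 1:
            raise ValueError("degree must be >= 1")
        self.lower = a
        self.upper = b
        self.degree = int(degree)
        self.interior = interior
        # clamped knot vector for degree-d B-splines
        self.knots = np.r_[[a] * (degree + 1), interior, [b] * (degree + 1)]
        self.n_basis = interior.size + degree + 1
        self._antiderivatives = []
        self._scales = np.empty(self.n_basis)
        for j in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            coef[j] = 1.0
            ad = BSpline(self.knots, coef, degree, extrapolate=False).antiderivative()
            lo, hi = ad(a), ad(b)
            self._antiderivatives.append(ad)
            self._scales[j] = hi - lo  # = (t_{j+d+1} - t_j) / (d + 1)
        self._offsets = np.array([ad(a) for ad in self._antiderivatives])
        self._design_cache: dict[bytes, np.ndarray] = {}

    @classmethod
    def from_data(cls, m, df: int = 4, degree: int = 3) -> "ISplineBasis":
        """Build a basis with ``df`` functions from observed quality values.

        Interior knots (``df - degree - 1`` of them, if any) are placed at
        quantiles of the distinct observed values; boundary knots at the
        observed min and max.  A degenerate (constant) ``m`` gets an
        artificial unit-width interval so the basis remains well defined.
        """
        if df < degree + 1:
            raise ValueError(f"df must be >= degree + 1, got df={df}, degree={degree}")
        m = np.asarray(m, dtype=float).ravel()
        if m.size == 0 or not np.all(np.isfinite(m)):
            raise ValueError("quality values must be non-empty and finite")
        a, b = float(m.min()), float(m.max())
        if b - a < 1e-10:
            b = a + 1.0
        n_interior = df - degree - 1
        if n_interior > 0:
            probs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
            interior = np.quantile(np.unique(m), probs)
            interior = interior[(interior > a) & (interior < b)]
        else:
            interior = ()
        return cls((a, b), interior, degree)

    def design(self, m) -> np.ndarray:
        """Evaluate the basis: returns an ``(len(m), n_basis)`` matrix.

        Each column is non-decreasing in ``m`` with values in ``[0, 1]``.
        """
        m = np.asarray(m, dtype=float).ravel()
        key = m.tobytes()  # repeated evaluation grids are memoised
        cached = self._design_cache.get(key)
        if cached is not None:
            return cached
        mc = np.clip(m, self.lower, self.upper)
        out = np.empty((mc.size, self.n_basis))
        for j, ad in enumerate(self._antiderivatives):
            out[:, j] = (ad(mc) - self._offsets[j]) / self._scales[j]
        # guard tiny negative round-off
        np.clip(out, 0.0, 1.0, out=out)
        out.setflags(write=False)
        if len(self._design_cache) > 16:
            self._design_cache.clear()
        self._design_cache[key] = out
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ISplineBasis(n_basis={self.n_basis}, degree={self.degree}, "
            f"domain=[{self.lower:g}, {self.upper:g}], "
            f"interior={list(self.interior)})"
        )
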
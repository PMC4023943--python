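"""Non-negative spline basis for release-time curves.

Release-time curves are modeled as f = Phi @ b with b >= 0.
Because every basis function here is non-negative and the rows of Phi sum
to one (partition of unity), non-negative coefficients guarantee a
non-negative curve — turning the curve's shape constraint into simple
bound constraints on b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import comb


@dataclass(frozen=True)
class SplineBasis:
    """Basis values Phi (D x K) at the release-event grid 1..D."""

    Phi: np.ndarray
    knots: np.ndarray

    @property
    def n_events(self) -> int:
        return self.Phi.shape[0]

    @property
    def df(self) -> int:
        return self.Phi.shape[1]

    def curve(self, b: np.ndarray) -> np.ndarray:
        return self.Phi @ np.asarray(b, dtype=float)


def build_basis(D: int, K: int) -> SplineBasis:
    """Cubic B-spline basis with K degrees of freedom on the grid 1..D.

    For K >= 4: clamped cubic B-splines with K-4 equally spaced interior
    knots.  For K < 4: Bernstein polynomials of degree K-1 (K=1 gives the
    constant basis).  All entries are non-negative and each row sums to 1.
    """
    if K < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {K}")
    if K > D:
        raise ValueError(f"degrees of freedom K={K} exceeds number of events D={D}")
    x = np.arange(1, D + 1, dtype=float)
    if K >= 4:
        interior = np.linspace(1.0, float(D), K - 4 + 2)[1:-1]
        knots = np.concatenate(([1.0] * 4, interior, [float(D)] * 4))
        Phi = BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()
    else:
        # Bernstein basis of degree K-1 on [1, D]
        u = (x - 1.0) / (D - 1.0) if D > 1 else np.zeros(1)
        k = np.arange(K)
        Phi = comb(K - 1, k)[None, :] * u[:, None] ** k * (1 - u[:, None]) ** (K - 1 - k)
        knots = np.array([1.0, float(D)])
    return SplineBasis(Phi=Phi, knots=knots)
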
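"""Basis constructions: orthogonal polynomials and periodic cubic B-splines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["OrthoPolyBasis", "ortho_poly", "cyclic_bspline_basis", "cyclic_diff_penalty"]


@dataclass
class OrthoPolyBasis:
    """Orthonormal polynomial basis fitted on training data, reusable on new data.

    Columns are built by the Forsythe three-term recurrence (the algorithm
    behind the usual ``poly()`` transform): on the training sample they are
    mutually orthogonal, mean-zero, and have unit Euclidean norm. The
    recurrence coefficients ``alpha`` and squared norms ``norm2`` are
    stored, so the identical transform can be applied to new data — test
    or anomaly rows are pushed through the training basis, never refitted.
    """

    degree: int = 2
    alpha: np.ndarray = field(default=None, repr=False)
    norm2: np.ndarray = field(default=None, repr=False)

    def fit(self, x) -> "OrthoPolyBasis":
        x = np.asarray(x, dtype=float)
        if len(np.unique(x)) <= self.degree:
            raise ValueError(
                f"need more than {self.degree} distinct values to build a "
                f"degree-{self.degree} orthogonal polynomial basis"
            )
        n = x.size
        alpha = np.empty(self.degree, dtype=float)
        norm2 = np.empty(self.degree + 1, dtype=float)
        f_prev = np.zeros(n)
        f_cur = np.ones(n)
        norm2[0] = n
        for j in range(self.degree):
            alpha[j] = np.sum(x * f_cur**2) / np.sum(f_cur**2)
            b = norm2[j] / norm2[j - 1] if j > 0 else 0.0
            f_next = (x - alpha[j]) * f_cur - b * f_prev
            norm2[j + 1] = np.sum(f_next**2)
            f_prev, f_cur = f_cur, f_next
        self.alpha, self.norm2 = alpha, norm2
        return self

    def transform(self, x) -> np.ndarray:
        """Evaluate the stored basis at ``x``; columns are poly1..poly<degree>."""
        if self.alpha is None:
            raise RuntimeError("basis not fitted")
        x = np.asarray(x, dtype=float)
        n = x.size
        cols = np.empty((n, self.degree))
        f_prev = np.zeros(n)
        f_cur = np.ones(n)
        for j in range(self.degree):
            b = self.norm2[j] / self.norm2[j - 1] if j > 0 else 0.0
            f_next = (x - self.alpha[j]) * f_cur - b * f_prev
            cols[:, j] = f_next / np.sqrt(self.norm2[j + 1])
            f_prev, f_cur = f_cur, f_next
        return cols

    def fit_transform(self, x) -> np.ndarray:
        return self.fit(x).transform(x)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "alpha": None if self.alpha is None else self.alpha.tolist(),
            "norm2": None if self.norm2 is None else self.norm2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrthoPolyBasis":
        b = cls(degree=int(d["degree"]))
        if d.get("alpha") is not None:
            b.alpha = np.asarray(d["alpha"], float)
            b.norm2 = np.asarray(d["norm2"], float)
        return b


def ortho_poly(x, degree: int = 2):
    """Fit an orthonormal polynomial basis and return ``(basis, columns)``."""
    b = OrthoPolyBasis(degree=degree)
    return b, b.fit_transform(x)


def cyclic_bspline_basis(day, knots) -> np.ndarray:
    """Periodic cubic B-spline design matrix.

    ``knots`` are strictly increasing breakpoints spanning one full period
    (first element = 0, last = period); values of ``day`` outside the
    period are wrapped. With K intervals the periodic basis has K
    functions, obtained by wrapping the ordinary cubic B-splines on a
    periodically extended knot vector. Rows sum to one (partition of
    unity), and every basis function — hence any curve built from them —
    matches in value and all derivatives across the period boundary.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 5:
        raise ValueError("need at least 5 knots (4 intervals) for a periodic cubic basis")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    period = knots[-1] - knots[0]
    x = knots[0] + np.mod(np.asarray(day, dtype=float) - knots[0], period)
    K = knots.size - 1
    t = np.concatenate([knots[:-1][-3:] - period, knots, knots[1:4] + period])
    full = BSpline.design_matrix(x, t, 3).toarray()  # (n, K+3)
    basis = full[:, :K].copy()
    basis[:, :3] += full[:, K : K + 3]
    return basis


def cyclic_diff_penalty(n_basis: int) -> np.ndarray:
    """Second-order difference penalty matrix with wrap-around.

    S = D'D where row i of D is the centred second difference
    c[i-1] - 2 c[i] + c[i+1] taken cyclically; the null space is the
    constant vector, so infinite smoothing flattens the curve to a
    constant on the linear-predictor scale.
    """
    D = np.zeros((n_basis, n_basis))
    for i in range(n_basis):
        D[i, (i - 1) % n_basis] = 1.0
        D[i, i] = -2.0
        D[i, (i + 1) % n_basis] = 1.0
    return D.T @ D
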
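"""Affine PCA dimension reduction for factor signatures.

Because the factor scores sum to one, the noiseless data columns live in an
affine subspace of dimension at most R - 1. Factors are therefore estimated
through their projected coordinates

    t_r = P (m_r - ybar),        m_r = P^T t_r + ybar,

where ``ybar`` is the empirical mean of the data columns and the rows of ``P``
are the leading principal eigenvectors of the empirical covariance of Y. The
non-negativity constraint on ``m_r`` translates into a polyhedral feasible set
for ``t_r``: every component of ``P^T t_r + ybar`` must be >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix, as_expression_matrix
from .exceptions import DimensionError


@dataclass
class ProjectedBasis:
    """The fitted affine dimension reduction.

    Attributes
    ----------
    P
        (K-1) x G projection matrix with orthonormal rows.
    back
        G x (K-1) back-projection matrix; equals ``P.T`` so that
        ``P @ back = I``.
    y_bar
        Empirical mean of the data columns (G-vector).
    K
        Subspace parameter; the working dimension is K - 1.
    """

    P: np.ndarray
    back: np.ndarray
    y_bar: np.ndarray
    K: int

    @property
    def dim(self) -> int:
        """Dimension of the projected coordinates (K - 1)."""
        return self.P.shape[0]

    def truncate(self, d: int) -> "ProjectedBasis":
        """Restrict to the leading ``d`` principal directions.

        The principal subspaces are nested, so a factor model with R factors
        can work in the leading R - 1 directions of one fitted basis without
        refitting the PCA.
        """
        if not 1 <= d <= self.dim:
            raise DimensionError(f"cannot truncate dimension {self.dim} to {d}")
        if d == self.dim:
            return self
        return ProjectedBasis(P=self.P[:d], back=self.back[:, :d],
                              y_bar=self.y_bar, K=d + 1)

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "y_bar": self.y_bar.tolist(),
            "P": self.P.tolist(),
        }


def fit_projection(Y, K: int) -> ProjectedBasis:
    """Fit the affine PCA basis of working dimension K - 1.

    Parameters
    ----------
    Y
        ExpressionMatrix or G x N array.
    K
        Subspace parameter, 2 <= K <= min(G, N). The projection keeps the
        K - 1 principal eigenvectors of the empirical covariance of Y.

    Raises
    ------
    DimensionError
        If the centered data have rank below K - 1.
    """
    values = as_expression_matrix(Y).values
    G, N = values.shape
    if not 2 <= K <= min(G, N):
        raise DimensionError(f"K={K} outside [2, min(G={G}, N={N})]")
    y_bar = values.mean(axis=1)
    centered = values - y_bar[:, None]
    # Left singular vectors of the centered data = eigenvectors of the
    # empirical covariance (1/N) C C^T, in decreasing eigenvalue order.
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    tol = s[0] * max(G, N) * np.finfo(np.float64).eps if s.size and s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if rank < K - 1:
        raise DimensionError(
            f"centered data have rank {rank}; cannot fit a {K - 1}-dimensional "
            f"subspace (need rank >= {K - 1})"
        )
    P = U[:, : K - 1].T.copy()
    # Fix each eigenvector's sign so its largest-magnitude entry is positive
    # (bit-reproducibility across LAPACK implementations).
    for d in range(P.shape[0]):
        j = int(np.argmax(np.abs(P[d])))
        if P[d, j] < 0:
            P[d] = -P[d]
    return ProjectedBasis(P=P, back=P.T.copy(), y_bar=y_bar, K=int(K))


def project_factor(basis: ProjectedBasis, m: np.ndarray) -> np.ndarray:
    """Return t = P (m - ybar)."""
    m = np.asarray(m, dtype=np.float64)
    if m.shape != basis.y_bar.shape:
        raise DimensionError(
            f"factor has length {m.shape}, expected {basis.y_bar.shape}"
        )
    return basis.P @ (m - basis.y_bar)


def backproject_factor(basis: ProjectedBasis, t: np.ndarray) -> np.ndarray:
    """Return m = P^T t + ybar."""
    t = np.asarray(t, dtype=np.float64)
    if t.shape != (basis.dim,):
        raise DimensionError(f"projected factor has shape {t.shape}, expected ({basis.dim},)")
    return basis.back @ t + basis.y_bar


def in_feasible_set(basis: ProjectedBasis, t: np.ndarray, tol: float = 0.0) -> bool:
    """True iff every component of the back-projected factor is >= -tol."""
    m = basis.back @ np.asarray(t, dtype=np.float64) + basis.y_bar
    return bool(np.all(m >= -tol))


def repair_to_feasible(basis: ProjectedBasis, t: np.ndarray, margin: float = 1e-9) -> np.ndarray:
    """Shrink t radially toward 0 until the back-projection is non-negative.

    t = 0 is always feasible because it back-projects to ybar, which is
    non-negative for non-negative data. The feasible set is convex and
    contains 0, so feasibility along the ray alpha * t is an interval
    [0, alpha_max]; the largest feasible alpha (shrunk by a small safety
    margin) is computed in closed form.
    """
    t = np.asarray(t, dtype=np.float64)
    m_dir = basis.back @ t
    neg = m_dir < 0
    if not np.any(neg):
        return t.copy()
    # alpha * m_dir_g + ybar_g >= 0 for every gene g with m_dir_g < 0.
    alpha = np.min(basis.y_bar[neg] / (-m_dir[neg]))
    alpha = min(1.0, alpha * (1.0 - margin))
    out = alpha * t
    # Guard against residual rounding: shrink a little further if needed.
    for _ in range(64):
        if in_feasible_set(basis, out):
            return out
        out *= 1.0 - 1e-6
    return np.zeros_like(t)
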
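"""Evaluation criteria for factor decompositions.

Implements the comparison metrics used to score an estimated decomposition
{M_est, A_est} against a ground truth {M_true, A_true}: per-factor mean square
error (MSE), global MSE of factor scores (GMSE), reconstruction error (RE),
spectral angle distance (SAD), global SAD (GSAD), and a Fisher linear
discriminant contrast for labeled sample groups. Because any unconstrained
factorization is only identified up to a permutation and positive rescaling of
its factors, estimated factors are aligned to the truth (minimum-total-SAD
assignment, optional least-squares rescaling) before MSE/GMSE are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datamodel import as_expression_matrix
from .exceptions import DimensionError


def sad(m_est: np.ndarray, m_true: np.ndarray) -> float:
    """Spectral angle distance: arccos of the cosine similarity, in [0, pi]."""
    m_est = np.asarray(m_est, dtype=np.float64).ravel()
    m_true = np.asarray(m_true, dtype=np.float64).ravel()
    if m_est.shape != m_true.shape:
        raise DimensionError("vectors have different lengths")
    ne = np.linalg.norm(m_est)
    nt = np.linalg.norm(m_true)
    if ne == 0.0 or nt == 0.0:
        raise ValueError("spectral angle undefined for a zero vector")
    c = float(m_est @ m_true) / (ne * nt)
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def reconstruction_error(Y, M: np.ndarray, A: np.ndarray) -> float:
    """RE = (1 / (N G)) sum_i ||y_i - M a_i||^2 (mean squared residual/entry)."""
    values = as_expression_matrix(Y).values
    if M.shape[0] != values.shape[0] or A.shape[1] != values.shape[1]:
        raise DimensionError("shapes of Y, M, A do not agree")
    resid = values - M @ A
    return float(np.einsum("ij,ij->", resid, resid)) / values.size


def gsad(Y, Y_hat) -> float:
    """Mean over samples of the per-column spectral angle between Y and Y_hat."""
    values = as_expression_matrix(Y).values
    hat = np.asarray(Y_hat, dtype=np.float64)
    if hat.shape != values.shape:
        raise DimensionError("Y and Y_hat have different shapes")
    return float(
        np.mean([sad(hat[:, i], values[:, i]) for i in range(values.shape[1])])
    )


def fisher_criterion(scores: np.ndarray, pos_mask: np.ndarray) -> float:
    """Fisher linear discriminant contrast between two labeled sample groups.

    (mu_pos - mu_neg)^2 / (N_pos var_pos + N_neg var_neg), with biased (1/n)
    group variances. Returns 0 when both groups are degenerate with equal
    means, +inf when the means differ but both variances vanish.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    mask = np.asarray(pos_mask, dtype=bool).ravel()
    if mask.shape != scores.shape:
        raise DimensionError("scores and pos_mask have different lengths")
    if not mask.any() or mask.all():
        raise ValueError("both groups must be non-empty")
    pos = scores[mask]
    neg = scores[~mask]
    num = float(pos.mean() - neg.mean()) ** 2
    den = pos.size * float(pos.var()) + neg.size * float(neg.var())
    if den == 0.0:
        return 0.0 if num == 0.0 else np.inf
    return num / den


@dataclass
class AlignmentResult:
    """Matching between estimated and ground-truth factors.

    Attributes
    ----------
    permutation
        Mapping estimated-factor index -> true-factor index (injective;
        estimated factors beyond the R_true best matches are dropped).
    scales
        Per-true-factor multipliers applied to the estimated factor before
        MSE/GMSE (all ones unless fitted).
    residual_sads
        Per-true-factor spectral angle after alignment.
    """

    permutation: dict[int, int]
    scales: np.ndarray
    residual_sads: np.ndarray

    def estimated_index(self, true_index: int) -> int:
        for e, t in self.permutation.items():
            if t == true_index:
                return e
        raise KeyError(true_index)


def align_factors(M_est: np.ndarray, M_true: np.ndarray, allow_scale: bool = False) -> AlignmentResult:
    """Best one-to-one assignment of estimated factors onto true factors.

    The assignment minimizes total spectral angle (a scale-free objective);
    when ``M_est`` has more columns than ``M_true`` only the best-matched
    subset is kept. With ``allow_scale`` each matched estimated factor gets a
    least-squares multiplier min_s ||s m_est - m_true||.
    """
    M_est = np.asarray(M_est, dtype=np.float64)
    M_true = np.asarray(M_true, dtype=np.float64)
    r_true = M_true.shape[1]
    r_est = M_est.shape[1]
    if r_est < r_true:
        raise DimensionError(
            f"need at least {r_true} estimated factors, got {r_est}"
        )
    cost = np.empty((r_true, r_est))
    for t in range(r_true):
        for e in range(r_est):
            cost[t, e] = sad(M_est[:, e], M_true[:, t])
    rows, cols = linear_sum_assignment(cost)
    permutation = {int(e): int(t) for t, e in zip(rows, cols)}
    scales = np.ones(r_true)
    residual = np.empty(r_true)
    for t, e in zip(rows, cols):
        residual[t] = cost[t, e]
        if allow_scale:
            denom = float(M_est[:, e] @ M_est[:, e])
            scales[t] = float(M_est[:, e] @ M_true[:, t]) / denom if denom > 0 else 1.0
    return AlignmentResult(permutation=permutation, scales=scales, residual_sads=residual)


def _aligned_pairs(alignment: AlignmentResult):
    return sorted(((t, e) for e, t in alignment.permutation.items()))


def mse_factors(M_est: np.ndarray, M_true: np.ndarray, alignment: AlignmentResult) -> np.ndarray:
    """Per-factor MSE_r = (1/G) ||s_r m_est - m_true||^2 after alignment."""
    M_est = np.asarray(M_est, dtype=np.float64)
    M_true = np.asarray(M_true, dtype=np.float64)
    if M_est.shape[0] != M_true.shape[0]:
        raise DimensionError("factor matrices have different numbers of genes")
    G = M_true.shape[0]
    out = np.empty(M_true.shape[1])
    for t, e in _aligned_pairs(alignment):
        diff = alignment.scales[t] * M_est[:, e] - M_true[:, t]
        out[t] = float(diff @ diff) / G
    return out


def gmse_scores(A_est: np.ndarray, A_true: np.ndarray, alignment: AlignmentResult) -> np.ndarray:
    """Per-factor GMSE_r = (1/N) sum_i (a_est - a_true)^2 after alignment.

    When factor scales were fitted the matched score rows are divided by the
    same scale (the factorization ambiguity {M S, S^-1 A} acts inversely on
    the scores).
    """
    A_est = np.asarray(A_est, dtype=np.float64)
    A_true = np.asarray(A_true, dtype=np.float64)
    if A_est.shape[1] != A_true.shape[1]:
        raise DimensionError("score matrices have different numbers of samples")
    N = A_true.shape[1]
    out = np.empty(A_true.shape[0])
    for t, e in _aligned_pairs(alignment):
        diff = A_est[e] / alignment.scales[t] - A_true[t]
        out[t] = float(diff @ diff) / N
    return out
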
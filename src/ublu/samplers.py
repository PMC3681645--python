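"""Gibbs conditionals: projected factors, score columns, noise variance.

All three conditionals are exact draws from the full conditionals of the
constrained mixing model. Truncated multivariate Gaussians (factor columns on
the positivity polyhedron, score columns on the simplex) are sampled by
systematic-scan coordinatewise Gibbs using a numerically robust univariate
truncated-normal primitive; one full scan is performed per outer iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import log_ndtr, ndtri_exp

from .datamodel import FactorModel, as_expression_matrix
from .exceptions import ConstraintError
from .model import PriorSpec
from .subspace import ProjectedBasis, in_feasible_set, repair_to_feasible

logger = logging.getLogger(__name__)

_LOG_TINY = np.log(np.finfo(np.float64).tiny)


# ---------------------------------------------------------------------------
# Truncated-normal primitive
# ---------------------------------------------------------------------------

def _truncnorm_draw(rng, mean, sd, lo, hi):
    """Vectorized draws from N(mean, sd^2) restricted to [lo, hi].

    Inverse-CDF sampling carried out in log-probability space on the mirrored
    lower tail, which stays accurate even for truncation regions many standard
    deviations into the tail (e.g. [8, 9] for a standard normal). Entries with
    lo >= hi degenerate to the midpoint of the (empty) interval bound.
    """
    mean, sd, lo, hi = np.broadcast_arrays(
        np.asarray(mean, dtype=np.float64),
        np.asarray(sd, dtype=np.float64),
        np.asarray(lo, dtype=np.float64),
        np.asarray(hi, dtype=np.float64),
    )
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    degenerate = ~(a < b)
    # Mirror intervals lying in the upper tail onto the lower tail where the
    # Gaussian CDF is computed without cancellation.
    with np.errstate(invalid="ignore"):
        mid = a + b
        flip = np.where(np.isnan(mid), a > 0, mid > 0)  # inf of mixed sign -> no flip
    a2 = np.where(flip, -b, a)
    b2 = np.where(flip, -a, b)
    a2 = np.where(degenerate, np.minimum(a2, b2) - 1.0, a2)
    with np.errstate(invalid="ignore", divide="ignore"):
        la = log_ndtr(a2)
        lb = log_ndtr(b2)
        u = rng.uniform(size=a2.shape)
        # p = (1-u) Phi(a2) + u Phi(b2), evaluated in log space.
        ratio = np.exp(np.clip(la - lb, None, 0.0))
        logp = lb + np.log(u + (1.0 - u) * ratio)
    logp = np.maximum(logp, _LOG_TINY)
    z = ndtri_exp(np.minimum(logp, -np.finfo(np.float64).tiny))
    z = np.where(flip, -z, z)
    x = mean + sd * z
    x = np.clip(x, lo, hi)
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            x = np.where(degenerate, 0.5 * (lo + hi), x)
    return x


def sample_truncated_normal(mean: float, var: float, lo: float, hi: float, rng) -> float:
    """One draw from the univariate N(mean, var) restricted to [lo, hi].

    ``lo`` may be -inf and ``hi`` may be +inf. Robust for truncation regions
    far in the tails.
    """
    if not var > 0:
        raise ValueError("variance must be positive")
    if not lo < hi:
        raise ValueError(f"empty truncation interval [{lo}, {hi}]")
    return float(_truncnorm_draw(rng, mean, np.sqrt(var), lo, hi))


# ---------------------------------------------------------------------------
# Chain state
# ---------------------------------------------------------------------------

@dataclass
class ChainState:
    """Current Gibbs state in projected coordinates.

    Attributes
    ----------
    T
        D x R projected factor matrix, where D = R - 1 is the working
        dimension (the leading D principal directions of the fitted basis;
        the principal subspaces are nested, so trans-dimensional moves grow
        or shrink D without refitting the PCA).
    A
        R x N factor score matrix.
    sigma2
        Current noise variance.
    E
        D x R prior mean matrix (tracks trans-dimensional moves).
    """

    T: np.ndarray
    A: np.ndarray
    sigma2: float
    E: np.ndarray

    @property
    def R(self) -> int:
        return self.T.shape[1]

    @property
    def dim(self) -> int:
        return self.T.shape[0]

    def factor_matrix(self, basis: ProjectedBasis) -> np.ndarray:
        """Back-project all columns: M = P^T T + ybar 1^T.

        Uses the leading ``self.dim`` columns of the back-projection when the
        state lives in a truncated subspace.
        """
        return basis.back[:, : self.dim] @ self.T + basis.y_bar[:, None]

    def copy(self) -> "ChainState":
        return ChainState(self.T.copy(), self.A.copy(), float(self.sigma2), self.E.copy())

    def to_factor_model(self, basis: ProjectedBasis) -> FactorModel:
        return FactorModel(self.factor_matrix(basis), self.A.copy(), self.sigma2)


def _model_like(state_or_model, basis: ProjectedBasis | None):
    """Accept a FactorModel or a ChainState (+basis); return (M, A, sigma2)."""
    if isinstance(state_or_model, ChainState):
        if basis is None:
            raise ConstraintError("a ProjectedBasis is required with a ChainState")
        return state_or_model.factor_matrix(basis), state_or_model.A, state_or_model.sigma2
    return state_or_model.M, state_or_model.A, state_or_model.sigma2


# ---------------------------------------------------------------------------
# Projected factor columns
# ---------------------------------------------------------------------------

@dataclass
class FactorConditional:
    """Gaussian conditional N(tau, Gamma) of one projected factor column."""

    Gamma: np.ndarray
    tau: np.ndarray


def factor_conditional(
    r: int,
    Y,
    state: ChainState,
    basis: ProjectedBasis,
    prior: PriorSpec,
) -> FactorConditional:
    """Conditional distribution of t_r given all other unknowns.

    With i.i.d. noise (Sigma = sigma2 I_G) and orthonormal projection rows,
    P Sigma^-1 P^T collapses to sigma^-2 I, so

        Gamma_r = (sum_i a_{r,i}^2 / sigma2 + 1/s2)^-1 I,
        tau_r   = Gamma_r (sum_i a_{r,i} P eps_{r,i} / sigma2 + e_r / s2),
        eps_{r,i} = y_i - a_{r,i} ybar - sum_{j != r} a_{j,i} m_j.
    """
    values = as_expression_matrix(Y).values
    basis = basis.truncate(state.dim)
    a_r = state.A[r]
    D = basis.dim
    prec = float(a_r @ a_r) / state.sigma2 + 1.0 / prior.s2
    Gamma = np.eye(D) / prec
    M = state.factor_matrix(basis)
    # eps columns: y_i - a_{r,i} ybar - (M a_i - a_{r,i} m_r)
    partial = M @ state.A - np.outer(M[:, r], a_r)
    eps = values - np.outer(basis.y_bar, a_r) - partial
    proj = basis.P @ (eps @ a_r)
    tau = Gamma @ (proj / state.sigma2 + prior.E[:, r] / prior.s2)
    return FactorConditional(Gamma=Gamma, tau=tau)


def _gibbs_scan_factor(
    tau: np.ndarray,
    Gamma: np.ndarray,
    t_init: np.ndarray,
    basis: ProjectedBasis,
    rng,
    tol: float = 0.0,
) -> np.ndarray:
    """One systematic coordinate scan of the polyhedron-truncated Gaussian.

    Coordinate bounds come from the linear inequalities P^T t + ybar >= 0; the
    back-projected signature is maintained incrementally.
    """
    D = tau.shape[0]
    prec = np.linalg.inv(Gamma)
    t = np.asarray(t_init, dtype=np.float64).copy()
    if not in_feasible_set(basis, t, tol=tol):
        t = repair_to_feasible(basis, t)
    m = basis.back @ t + basis.y_bar
    for d in range(D):
        bcol = basis.back[:, d]
        m_wo = m - bcol * t[d]
        pos = bcol > 0
        neg = bcol < 0
        lo = np.max(-(m_wo[pos] + tol) / bcol[pos]) if np.any(pos) else -np.inf
        hi = np.min(-(m_wo[neg] + tol) / bcol[neg]) if np.any(neg) else np.inf
        cvar = 1.0 / prec[d, d]
        cmean = tau[d] - cvar * (prec[d] @ (t - tau) - prec[d, d] * (t[d] - tau[d]))
        if lo < hi:
            t_new = float(_truncnorm_draw(rng, cmean, np.sqrt(cvar), lo, hi))
        else:  # numerically empty slice: stay put, clamped into the interval
            t_new = float(np.clip(t[d], min(lo, hi), max(lo, hi)))
        m = m_wo + bcol * t_new
        t[d] = t_new
    return t


def sample_factor_column(
    r: int,
    Y,
    state: ChainState,
    basis: ProjectedBasis,
    prior: PriorSpec,
    rng,
    positivity: bool = True,
    tol: float = 0.0,
) -> np.ndarray:
    """Draw a new projected factor column t_r from its full conditional.

    With positivity active the draw is truncated to the feasible polyhedron by
    one coordinatewise Gibbs scan starting at the current column (repaired to
    feasibility if needed); otherwise it is an exact Gaussian draw.
    """
    cond = factor_conditional(r, Y, state, basis, prior)
    if not positivity:
        L = np.linalg.cholesky(cond.Gamma)
        return cond.tau + L @ rng.standard_normal(cond.tau.shape[0])
    return _gibbs_scan_factor(cond.tau, cond.Gamma, state.T[:, r],
                              basis.truncate(state.dim), rng, tol=tol)


# ---------------------------------------------------------------------------
# Score columns
# ---------------------------------------------------------------------------

@dataclass
class ScoreConditional:
    """Gaussian conditional of the free score coordinates of one sample."""

    mean: np.ndarray
    cov: np.ndarray


def _stable_cho(Gm: np.ndarray, context: str):
    """Cholesky with ridge stabilization for (near-)duplicate factors."""
    try:
        return cho_factor(Gm)
    except np.linalg.LinAlgError:
        pass
    ridge = 1e-10 * max(float(np.trace(Gm)) / max(Gm.shape[0], 1), 1.0)
    for _ in range(12):
        try:
            out = cho_factor(Gm + ridge * np.eye(Gm.shape[0]))
            logger.warning(
                "%s: singular normal matrix; ridge-stabilized with %.3e", context, ridge
            )
            return out
        except np.linalg.LinAlgError:
            ridge *= 10.0
    raise ConstraintError(f"{context}: normal matrix is irreparably singular")


def score_conditional(i: int, Y, model, basis: ProjectedBasis | None = None) -> ScoreConditional:
    """Conditional of a_{1:R-1, i} (last score expressed as one minus the rest).

    With Mbar = M[:, :R-1] - m_R 1^T:

        cov  = sigma2 (Mbar^T Mbar)^-1,
        mean = (Mbar^T Mbar)^-1 Mbar^T (y_i - m_R),

    derived from y_i = Mbar a_{1:R-1,i} + m_R + n_i.
    """
    values = as_expression_matrix(Y).values
    M, _, sigma2 = _model_like(model, basis)
    R = M.shape[1]
    if R < 2:
        raise ConstraintError("score conditional requires R >= 2")
    Mbar = M[:, : R - 1] - M[:, -1:]
    Gm = Mbar.T @ Mbar
    cho = _stable_cho(Gm, "score_conditional")
    eye = np.eye(R - 1)
    cov = sigma2 * cho_solve(cho, eye)
    mean = cho_solve(cho, Mbar.T @ (values[:, i] - M[:, -1]))
    return ScoreConditional(mean=mean, cov=cov)


def _scan_scores(
    X: np.ndarray,
    U: np.ndarray,
    prec: np.ndarray,
    rng,
    lower_zero: bool,
    simplex_upper: bool,
) -> np.ndarray:
    """One systematic coordinate scan over the free score rows, vectorized
    across samples (score columns are conditionally independent given M)."""
    f, n = X.shape
    for d in range(f):
        cvar = 1.0 / prec[d, d]
        resid = prec[d] @ (X - U) - prec[d, d] * (X[d] - U[d])
        cmean = U[d] - cvar * resid
        if simplex_upper:
            hi = 1.0 - (X.sum(axis=0) - X[d])
            hi = np.maximum(hi, 0.0)
        else:
            hi = np.full(n, np.inf)
        lo = np.zeros(n) if lower_zero else np.full(n, -np.inf)
        X[d] = _truncnorm_draw(rng, cmean, np.sqrt(cvar), lo, hi)
    return X


def sample_score_columns(Y, model, rng, mode: str = "both", basis=None) -> np.ndarray:
    """Draw a full new score matrix A (all columns) from its conditional.

    ``mode`` selects which constraints are active:

    * ``both``            -- columns on the simplex (free coords in [0, 1-rest],
      last coordinate one minus the rest);
    * ``sum_to_one_only`` -- last coordinate one minus the rest, no bounds;
    * ``positivity_only`` -- all R coordinates free but >= 0;
    * ``none``            -- unconstrained exact Gaussian draw.
    """
    values = as_expression_matrix(Y).values
    M, A, sigma2 = _model_like(model, basis)
    R, N = A.shape
    if R < 2:
        raise ConstraintError("score sampling requires R >= 2")
    sum_to_one = mode in ("both", "sum_to_one_only")
    positivity = mode in ("both", "positivity_only")

    if sum_to_one:
        Mbar = M[:, : R - 1] - M[:, -1:]
        Gm = Mbar.T @ Mbar
        cho = _stable_cho(Gm, "sample_score_columns")
        U = cho_solve(cho, Mbar.T @ (values - M[:, -1:]))
        prec = Gm / sigma2
        X = A[: R - 1].copy()
        if positivity:
            X = np.clip(X, 0.0, None)
            tot = X.sum(axis=0)
            over = tot > 1.0
            if np.any(over):
                X[:, over] *= (1.0 - 1e-12) / tot[over]
        X = _scan_scores(X, U, prec, rng, lower_zero=positivity, simplex_upper=positivity)
        last = 1.0 - X.sum(axis=0)
        if positivity:
            last = np.maximum(last, 0.0)
        return np.vstack([X, last])

    Gm = M.T @ M
    cho = _stable_cho(Gm, "sample_score_columns")
    U = cho_solve(cho, M.T @ values)
    if positivity:
        prec = Gm / sigma2
        X = np.clip(A.copy(), 0.0, None)
        return _scan_scores(X, U, prec, rng, lower_zero=True, simplex_upper=False)
    # fully unconstrained: exact multivariate Gaussian draw per sample
    cov = sigma2 * cho_solve(cho, np.eye(R))
    L = np.linalg.cholesky(cov + 1e-14 * np.eye(R))
    return U + L @ rng.standard_normal((R, N))


def sample_score_column(i: int, Y, model, rng, mode: str = "both", basis=None) -> np.ndarray:
    """Draw a new score column a_i; see :func:`sample_score_columns`."""
    values = as_expression_matrix(Y).values
    M, A, sigma2 = _model_like(model, basis)
    sub_Y = values[:, [i]]
    sub_model = FactorModel(M, A[:, [i]], sigma2)
    return sample_score_columns(sub_Y, sub_model, rng, mode=mode)[:, 0]


# ---------------------------------------------------------------------------
# Noise variance
# ---------------------------------------------------------------------------

def draw_sigma2(ssr_val: float, gn: int, rng, floor: float = 1e-12) -> float:
    """Draw sigma2 ~ InverseGamma(GN/2, SSR/2); degenerate SSR -> floor."""
    if ssr_val <= 0.0:
        logger.warning("zero residual: sigma2 degenerate, returning floor %.1e", floor)
        return floor
    shape = gn / 2.0
    g = rng.standard_gamma(shape)
    if g <= 0.0:
        g = np.finfo(np.float64).tiny
    return max((ssr_val / 2.0) / g, floor)


def sample_sigma2(Y, model, rng, basis=None, floor: float = 1e-12) -> float:
    """Draw the noise variance from its inverse-Gamma full conditional."""
    values = as_expression_matrix(Y).values
    M, A, _ = _model_like(model, basis)
    resid = values - M @ A
    ssr_val = float(np.einsum("ij,ij->", resid, resid))
    return draw_sigma2(ssr_val, values.size, rng, floor=floor)
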
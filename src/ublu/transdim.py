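"""Birth, death, and switch moves for inferring the number of factors.

At each outer iteration one of three trans-dimensional proposals is drawn:

* birth  -- append a freshly generated signature and give it a Beta(1, R)
  share of every sample's scores (old scores rescaled so columns still sum to
  one); the working dimension grows by one along with the factor count;
* death  -- remove the most redundant factor (smallest score-weighted distance
  to the convex hull of the other signatures) and redistribute its scores onto
  the remaining factors in the simplex proportions that best reconstruct its
  signature; the working dimension shrinks by one;
* switch -- replace a uniformly chosen signature with a freshly generated one,
  keeping its scores.

Each proposal is accepted with probability min(1, rho) where rho is the
*empirical* likelihood ratio between the new and the current state: the
geometric mean over the G x N matrix entries of the pointwise likelihood
ratio, i.e. exp(delta_loglik / (G N)). The total-likelihood ratio is also
reported on every proposal, but at gene-chip dimensions it is numerically
degenerate (astronomically small for any dimension change once the within-R
Gibbs has adapted), which would freeze the factor count; the per-entry ratio
measures the same fit comparison per observation, independent of matrix size.
No reversible-jump proposal Jacobians are applied, so the chain targets the
posterior over R only approximately -- a deliberate property of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import nnls

from .datamodel import as_expression_matrix
from .exceptions import ConstraintError
from .metrics import sad
from .model import PriorSpec
from .samplers import ChainState
from .subspace import ProjectedBasis, backproject_factor, repair_to_feasible

logger = logging.getLogger(__name__)

MOVE_KINDS = ("birth", "death", "switch")


@dataclass
class MoveProposal:
    """A proposed trans-dimensional transition.

    ``log_ratio`` is the per-entry (geometric-mean) log-likelihood ratio
    new - current, i.e. ``delta_loglik / (G N)``; it is the quantity fed to
    the accept rule. ``delta_loglik`` is the full log-likelihood difference.
    ``ssr`` is the proposal's sum of squared residuals (cached so the
    accepting caller need not recompute it).
    """

    kind: str
    state: ChainState
    log_ratio: float
    ssr: float
    delta_loglik: float = 0.0


def choose_move(R: int, r_max: int, move_probs, rng) -> str:
    """Pick birth/death/switch with the configured probabilities.

    Death is disabled at R = 2 and birth at R = r_max; the remaining mass is
    renormalized.
    """
    if not 2 <= R <= r_max:
        raise ConstraintError(f"R={R} outside [2, {r_max}]")
    b, d, s = (float(p) for p in move_probs)
    if R <= 2:
        d = 0.0
    if R >= r_max:
        b = 0.0
    total = b + d + s
    if total <= 0:
        raise ConstraintError("no admissible move has positive probability")
    return str(rng.choice(MOVE_KINDS, p=np.array([b, d, s]) / total))


def propose_signature(
    Y,
    basis: ProjectedBasis,
    state: ChainState,
    prior: PriorSpec,
    rng,
    exclude: Optional[int] = None,
    min_sad: float = 0.05,
    max_tries: int = 50,
    positivity: bool = True,
    dim: Optional[int] = None,
):
    """Generate a feasible signature sufficiently distinct from existing ones.

    A uniformly chosen data column is projected onto the leading ``dim``
    principal directions (the current state's working dimension unless a move
    is growing it), jittered with Gaussian noise of variance s2/10, repaired
    to feasibility, and kept if its back-projected signature is at least
    ``min_sad`` radians (spectral angle) away from every retained factor.
    Returns (t, m) or None if ``max_tries`` draws all fail.
    """
    values = as_expression_matrix(Y).values
    N = values.shape[1]
    sub = basis.truncate(dim if dim is not None else state.dim)
    M_cur = state.factor_matrix(basis)
    keep = [j for j in range(state.R) if j != exclude]
    jitter_sd = np.sqrt(prior.s2 / 10.0)
    for _ in range(max_tries):
        j = int(rng.integers(N))
        t = sub.P @ (values[:, j] - sub.y_bar) + jitter_sd * rng.standard_normal(sub.dim)
        if positivity:
            t = repair_to_feasible(sub, t)
        m = backproject_factor(sub, t)
        if not np.any(m):
            continue
        if all(sad(m, M_cur[:, c]) > min_sad for c in keep):
            return t, m
    return None


def _delta_loglik(Y_values: np.ndarray, new_state: ChainState, basis, ssr_old: float):
    """Log-likelihood ratios at the current sigma2, plus the proposal's SSR.

    Returns (per-entry log ratio, full log ratio, SSR of the proposal). The
    per-entry ratio -- the full ratio divided by the number of matrix entries
    G N -- is the empirical acceptance quantity: it compares how well the two
    states explain a representative observation entry, independent of the
    matrix size.
    """
    M_new = new_state.factor_matrix(basis)
    resid = Y_values - M_new @ new_state.A
    ssr_new = float(np.einsum("ij,ij->", resid, resid))
    delta = (ssr_old - ssr_new) / (2.0 * new_state.sigma2)
    return delta / Y_values.size, delta, ssr_new


def propose_birth(
    state: ChainState,
    Y,
    basis: ProjectedBasis,
    prior: PriorSpec,
    rng,
    ssr_old: Optional[float] = None,
    min_sad: float = 0.05,
    max_tries: int = 50,
    positivity: bool = True,
) -> Optional[MoveProposal]:
    """Propose R -> R + 1. Returns None when no distinct signature is found."""
    values = as_expression_matrix(Y).values
    dim_new = state.dim + 1
    if dim_new > basis.dim:
        raise ConstraintError("birth move would exceed the fitted basis dimension")
    sig = propose_signature(
        Y, basis, state, prior, rng,
        min_sad=min_sad, max_tries=max_tries, positivity=positivity, dim=dim_new,
    )
    if sig is None:
        logger.debug("birth proposal aborted: no distinct feasible signature")
        return None
    t_new, _ = sig
    N = state.A.shape[1]
    w = rng.beta(1.0, state.R, size=N)
    A_new = np.vstack([state.A * (1.0 - w), w])
    pad = np.zeros((1, state.R))  # existing factors have no component in the new direction
    new_state = ChainState(
        T=np.column_stack([np.vstack([state.T, pad]), t_new]),
        A=A_new,
        sigma2=state.sigma2,
        E=np.column_stack([np.vstack([state.E, pad]), t_new]),
    )
    if ssr_old is None:
        M_old = state.factor_matrix(basis)
        r_old = values - M_old @ state.A
        ssr_old = float(np.einsum("ij,ij->", r_old, r_old))
    log_ratio, delta, ssr_new = _delta_loglik(values, new_state, basis, ssr_old)
    return MoveProposal("birth", new_state, log_ratio, ssr_new, delta)


def _simplex_coefficients(M_rest: np.ndarray, m_r: np.ndarray) -> np.ndarray:
    """Represent a removed signature on the remaining ones.

    Fully constrained least squares: beta >= 0 with sum(beta) = 1, computed by
    non-negative least squares on a sum-augmented system and renormalized. If
    the removed factor lies in the convex hull of the others the fit is exact
    and the death move below is (near-)lossless.
    """
    scale = float(np.abs(M_rest).max())
    if scale == 0.0:
        return np.full(M_rest.shape[1], 1.0 / M_rest.shape[1])
    delta = 10.0 * scale
    aug = np.vstack([M_rest, np.full(M_rest.shape[1], delta)])
    target = np.append(m_r, delta)
    beta, _ = nnls(aug, target)
    total = beta.sum()
    if total <= 0.0:
        return np.full(M_rest.shape[1], 1.0 / M_rest.shape[1])
    return beta / total


def propose_death(
    state: ChainState,
    Y,
    basis: ProjectedBasis,
    rng,
    ssr_old: Optional[float] = None,
    sum_to_one: bool = True,
) -> MoveProposal:
    """Propose R -> R - 1 by removing a uniformly chosen factor.

    The removed factor's scores are redistributed onto the remaining factors
    in the simplex proportions that best reconstruct its signature, keeping
    every score column on the simplex; a redundant factor (one expressible as
    a convex combination of the others) therefore dies at almost no
    likelihood cost, while removing a genuine vertex is heavily penalized.
    """
    if state.R <= 2:
        raise ConstraintError("death move requires R > 2")
    values = as_expression_matrix(Y).values
    if sum_to_one:
        # target the most redundant factor: the one whose score-weighted
        # distance to the convex hull of the remaining signatures is smallest
        M_cur = state.factor_matrix(basis)
        weights = np.einsum("rn,rn->r", state.A, state.A)
        costs = np.empty(state.R)
        betas = []
        for k in range(state.R):
            beta_k = _simplex_coefficients(np.delete(M_cur, k, axis=1), M_cur[:, k])
            err = np.delete(M_cur, k, axis=1) @ beta_k - M_cur[:, k]
            costs[k] = weights[k] * float(err @ err)
            betas.append(beta_k)
        r = int(np.argmin(costs))
        beta = betas[r]
        A_new = np.delete(state.A, r, axis=0) + beta[:, None] * state.A[r][None, :]
    else:
        r = int(rng.integers(state.R))
        A_new = np.delete(state.A, r, axis=0)
    # drop the last working dimension along with the factor (D tracks R - 1)
    new_state = ChainState(
        T=np.delete(state.T, r, axis=1)[:-1],
        A=A_new,
        sigma2=state.sigma2,
        E=np.delete(state.E, r, axis=1)[:-1],
    )
    if ssr_old is None:
        M_old = state.factor_matrix(basis)
        r_old = values - M_old @ state.A
        ssr_old = float(np.einsum("ij,ij->", r_old, r_old))
    log_ratio, delta, ssr_new = _delta_loglik(values, new_state, basis, ssr_old)
    return MoveProposal("death", new_state, log_ratio, ssr_new, delta)


def propose_switch(
    state: ChainState,
    Y,
    basis: ProjectedBasis,
    prior: PriorSpec,
    rng,
    ssr_old: Optional[float] = None,
    min_sad: float = 0.05,
    max_tries: int = 50,
    positivity: bool = True,
) -> Optional[MoveProposal]:
    """Propose replacing one signature with a fresh one (R unchanged).

    The replaced factor keeps its scores. The signature generator redraws
    until the candidate is distinct from every retained factor; if that fails
    the proposal is aborted (None), as for birth.
    """
    values = as_expression_matrix(Y).values
    r = int(rng.integers(state.R))
    sig = propose_signature(
        Y, basis, state, prior, rng,
        exclude=r, min_sad=min_sad, max_tries=max_tries, positivity=positivity,
    )
    if sig is None:
        logger.debug("switch proposal aborted: no distinct feasible signature")
        return None
    t_new, _ = sig
    T_new = state.T.copy()
    T_new[:, r] = t_new
    E_new = state.E.copy()
    E_new[:, r] = t_new
    new_state = ChainState(T=T_new, A=state.A.copy(), sigma2=state.sigma2, E=E_new)
    if ssr_old is None:
        M_old = state.factor_matrix(basis)
        r_old = values - M_old @ state.A
        ssr_old = float(np.einsum("ij,ij->", r_old, r_old))
    log_ratio, delta, ssr_new = _delta_loglik(values, new_state, basis, ssr_old)
    return MoveProposal("switch", new_state, log_ratio, ssr_new, delta)


def accept(proposal: MoveProposal, rng) -> bool:
    """Accept with probability min(1, exp(log_ratio))."""
    if proposal.log_ratio >= 0:
        return True
    if np.isneginf(proposal.log_ratio):
        return False
    return bool(rng.uniform() < np.exp(proposal.log_ratio))
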
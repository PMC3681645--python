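"""Full Gibbs sweep: trans-dimensional move, factor scan, score scan, noise
variance draw; chain storage; MAP estimators; reconstruction-error trace.

The chain is initialized from a maximal-simplex-volume endmember search on the
projected data (the standard geometric initialization for linear unmixing):
the selected data projections serve both as prior means and as the starting
factor matrix. Kept samples are stored in projected form (T, A, sigma2,
posterior score) and back-projected on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import FactorModel, RunConfig, as_expression_matrix
from .exceptions import DimensionError, UnmixError
from .model import PriorSpec, posterior_score_terms
from .samplers import (
    ChainState,
    _gibbs_scan_factor,
    draw_sigma2,
    sample_score_columns,
)
from .subspace import ProjectedBasis, fit_projection, repair_to_feasible
from .transdim import (
    MOVE_KINDS,
    accept,
    choose_move,
    propose_birth,
    propose_death,
    propose_switch,
)

logger = logging.getLogger(__name__)


@dataclass
class KeptSample:
    """One post-burn-in chain state, stored in projected coordinates."""

    T: np.ndarray
    A: np.ndarray
    sigma2: float
    score: float

    @property
    def R(self) -> int:
        return self.T.shape[1]


@dataclass
class ChainTrace:
    """Stored output of a Gibbs run."""

    R_samples: np.ndarray
    kept: list[KeptSample]
    re_trace: np.ndarray
    acceptance: dict
    config: RunConfig
    basis: ProjectedBasis
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def r_histogram(self) -> dict[int, int]:
        """Counts of the post-burn-in factor-count samples."""
        post = self.R_samples[self.config.n_bi:]
        values, counts = np.unique(post, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def r_posterior(self) -> dict[int, float]:
        """Posterior frequencies N_k / N_r of the factor count."""
        hist = self.r_histogram()
        total = sum(hist.values())
        return {k: c / total for k, c in hist.items()}


def nfindr_endmembers(Ytil: np.ndarray, R: int) -> list[int]:
    """Greedy maximal-simplex-volume selection of R projected data columns.

    Starts from the column farthest from the projected centroid, then
    repeatedly adds the column with the largest orthogonal distance to the
    affine hull of the current selection (each addition maximizes the
    incremental simplex volume).
    """
    Ytil = np.asarray(Ytil, dtype=np.float64)
    D, N = Ytil.shape
    if R > N:
        raise DimensionError(f"cannot select {R} endmembers from {N} samples")
    centroid = Ytil.mean(axis=1)
    dist0 = np.linalg.norm(Ytil - centroid[:, None], axis=0)
    selected = [int(np.argmax(dist0))]
    base = Ytil[:, selected[0]]
    Q = np.zeros((D, 0))
    for _ in range(1, R):
        resid = Ytil - base[:, None]
        if Q.shape[1]:
            resid = resid - Q @ (Q.T @ resid)
        norms = np.linalg.norm(resid, axis=0)
        norms[selected] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= 1e-12 * max(1.0, np.linalg.norm(Ytil)):
            raise DimensionError(
                f"projected data support only {len(selected)} affinely "
                f"independent endmembers; requested {R}"
            )
        selected.append(j)
        v = Ytil[:, j] - base
        if Q.shape[1]:
            v = v - Q @ (Q.T @ v)
        Q = np.column_stack([Q, v / np.linalg.norm(v)])
    return selected


def _factor_scan(
    state: ChainState,
    basis: ProjectedBasis,
    s2: float,
    Ytil: np.ndarray,
    pbar: np.ndarray,
    rng,
    positivity: bool,
    tol: float,
) -> None:
    """Update every projected factor column in place (one Gibbs sweep).

    Uses the collapsed conditional (orthonormal projection rows, i.i.d.
    noise): Gamma_r is a scalar multiple of the identity and the data term of
    tau_r only needs the R x R score Gram matrix and the projected data.
    """
    A = state.A
    D = state.dim
    sub = basis.truncate(D)
    Ysub = Ytil[:D]
    psub = pbar[:D]
    S = A @ A.T
    C = Ysub @ A.T
    eye = np.eye(D)
    for r in range(state.R):
        prec = S[r, r] / state.sigma2 + 1.0 / s2
        gamma = 1.0 / prec
        # sum_i a_{r,i} P eps_{r,i} in projected coordinates
        vec = C[:, r] - S[r, r] * psub - (state.T + psub[:, None]) @ S[r] \
            + S[r, r] * (state.T[:, r] + psub)
        tau = gamma * (vec / state.sigma2 + state.E[:, r] / s2)
        if positivity:
            t_new = _gibbs_scan_factor(tau, gamma * eye, state.T[:, r], sub, rng, tol=tol)
        else:
            t_new = tau + np.sqrt(gamma) * rng.standard_normal(D)
        state.T[:, r] = t_new


def run_ublu(Y, config: RunConfig) -> ChainTrace:
    """Run the full (optionally supervised) Gibbs sampler.

    Each iteration performs one trans-dimensional move (skipped in supervised
    mode), one full scan of projected factor columns, one full scan of score
    columns, and one noise-variance draw; the factor count and reconstruction
    error are recorded every iteration, full states after burn-in. Identical
    seed + config + input give identical output.
    """
    Y = as_expression_matrix(Y)
    values = Y.values
    G, N = values.shape
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.r_max > min(G, N):
        raise DimensionError(
            f"r_max={cfg.r_max} exceeds min(G={G}, N={N}); the working "
            "subspace cannot be fitted"
        )
    # The chain never needs more than r_max - 1 (or fixed_r - 1) principal
    # directions; on (near-)noise-free data the centered rank may be smaller
    # still, in which case the admissible factor counts are capped at rank+1.
    centered = values - values.mean(axis=1, keepdims=True)
    svals = np.linalg.svd(centered, compute_uv=False)
    tol = svals[0] * max(G, N) * np.finfo(np.float64).eps if svals[0] > 0 else 0.0
    rank = int(np.sum(svals > tol))
    if cfg.fixed_r is not None and cfg.fixed_r - 1 > rank:
        raise DimensionError(
            f"fixed_r={cfg.fixed_r} needs {cfg.fixed_r - 1} principal "
            f"directions but the centered data have rank {rank}"
        )
    r_cap = min(cfg.r_max, rank + 1)
    if r_cap < cfg.r_max:
        logger.info("centered data have rank %d: capping the factor count at %d",
                    rank, r_cap)
    basis = fit_projection(Y, K=r_cap)
    Ytil = basis.P @ values
    pbar = basis.P @ basis.y_bar
    positivity = cfg.positivity
    sum_to_one = cfg.sum_to_one

    R0 = cfg.fixed_r if cfg.fixed_r is not None else r_cap
    D0 = R0 - 1  # working dimension tracks the current factor count
    sub0 = basis.truncate(D0)
    endmembers = nfindr_endmembers(Ytil[:D0], R0)
    E = Ytil[:D0, endmembers].copy()
    if positivity:
        for r in range(R0):
            E[:, r] = repair_to_feasible(sub0, E[:, r])
    state = ChainState(
        T=E.copy(),
        A=np.full((R0, N), 1.0 / R0),
        sigma2=1.0,
        E=E,
    )
    M = state.factor_matrix(basis)
    resid = values - M @ state.A
    ssr_val = float(np.einsum("ij,ij->", resid, resid))
    state.sigma2 = max(ssr_val / (G * N), cfg.sigma2_floor)

    acceptance = {k: {"proposed": 0, "accepted": 0, "aborted": 0} for k in MOVE_KINDS}
    R_samples = np.empty(cfg.n_mc, dtype=np.int64)
    re_trace = np.empty(cfg.n_mc)
    kept: list[KeptSample] = []

    for it in range(cfg.n_mc):
        if cfg.fixed_r is None:
            prior = PriorSpec(state.E, cfg.s2, cfg.nu, cfg.r_max)
            kind = choose_move(state.R, r_cap, cfg.move_probs, rng)
            if kind == "birth":
                prop = propose_birth(
                    state, Y, basis, prior, rng, ssr_old=ssr_val,
                    min_sad=cfg.distinct_sad, max_tries=cfg.proposal_max_tries,
                    positivity=positivity,
                )
            elif kind == "death":
                prop = propose_death(
                    state, Y, basis, rng, ssr_old=ssr_val, sum_to_one=sum_to_one,
                )
            else:
                prop = propose_switch(
                    state, Y, basis, prior, rng, ssr_old=ssr_val,
                    min_sad=cfg.distinct_sad, max_tries=cfg.proposal_max_tries,
                    positivity=positivity,
                )
            if prop is None:
                acceptance[kind]["aborted"] += 1
            else:
                acceptance[kind]["proposed"] += 1
                if accept(prop, rng):
                    acceptance[kind]["accepted"] += 1
                    state = prop.state
                    ssr_val = prop.ssr

        _factor_scan(state, basis, cfg.s2, Ytil, pbar, rng,
                     positivity, cfg.feasibility_tol)
        M = state.factor_matrix(basis)
        state.A = sample_score_columns(
            values, FactorModel(M, state.A, state.sigma2), rng,
            mode=cfg.constraint_mode,
        )
        resid = values - M @ state.A
        ssr_val = float(np.einsum("ij,ij->", resid, resid))
        state.sigma2 = draw_sigma2(ssr_val, G * N, rng, floor=cfg.sigma2_floor)

        re = ssr_val / (G * N)
        if not np.isfinite(re) or not np.isfinite(state.sigma2):
            raise UnmixError(
                f"non-finite chain state at iteration {it + 1}: "
                f"RE={re}, sigma2={state.sigma2}, R={state.R}"
            )
        R_samples[it] = state.R
        re_trace[it] = re
        if it >= cfg.n_bi:
            score = posterior_score_terms(
                ssr_val, state.sigma2, state.T, state.E, cfg.s2,
                state.R, cfg.r_max, G, N,
            )
            kept.append(KeptSample(state.T.copy(), state.A.copy(),
                                   float(state.sigma2), float(score)))
        if cfg.log_every and (it + 1) % cfg.log_every == 0:
            logger.info("iteration %d/%d: R=%d RE=%.6g sigma2=%.6g",
                        it + 1, cfg.n_mc, state.R, re, state.sigma2)

    return ChainTrace(
        R_samples=R_samples,
        kept=kept,
        re_trace=re_trace,
        acceptance=acceptance,
        config=cfg,
        basis=basis,
        gene_ids=list(Y.gene_ids),
        sample_ids=list(Y.sample_ids),
    )


def estimate_R_map(trace: ChainTrace) -> int:
    """MAP estimate of the factor count: the most frequent post-burn-in R.

    Ties are broken toward the smaller count.
    """
    hist = trace.r_histogram()
    if not hist:
        raise UnmixError("empty post-burn-in trace")
    best = max(sorted(hist), key=lambda k: hist[k])  # sorted -> ties to smaller k
    return int(best)


def estimate_joint_map(trace: ChainTrace, r_hat: int) -> FactorModel:
    """Joint MAP estimate: the stored sample with R = r_hat maximizing the
    posterior score (first maximizer on ties, i.e. the earliest iteration)."""
    candidates = [s for s in trace.kept if s.R == r_hat]
    if not candidates:
        raise UnmixError(
            f"no stored post-burn-in sample has R={r_hat}; run a longer chain"
        )
    scores = np.array([s.score for s in candidates])
    best = candidates[int(np.argmax(scores))]
    d = best.T.shape[0]
    M = trace.basis.back[:, :d] @ best.T + trace.basis.y_bar[:, None]
    return FactorModel(M, best.A.copy(), best.sigma2)


def reconstruction_trace(trace: ChainTrace) -> np.ndarray:
    """Per-iteration reconstruction error RE^(t) (mean squared residual)."""
    return np.asarray(trace.re_trace)
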
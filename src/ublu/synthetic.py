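"""Ground-truth simulation scenarios for parameter-recovery testing.

Three factor geometries are provided:

* ``peaky``               -- each signature is a small positive baseline plus a
  disjoint block of high-amplitude genes (a sparse, gene-specific signature);
* ``orthogonal``          -- orthonormalized Gaussian signatures, signs
  unconstrained (deliberately violates the positivity assumption);
* ``orthogonal_positive`` -- non-negative signatures with disjoint supports
  (disjoint support implies exact orthogonality).

Scores are drawn column-wise from a flat Dirichlet on the simplex and the
mixture is corrupted with i.i.d. Gaussian noise calibrated to a target
signal-to-noise ratio; the default dimensions are G = 512 genes, N = 128
samples, R = 3 factors at 20 dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import ExpressionMatrix
from .exceptions import ConfigError

logger = logging.getLogger(__name__)

SCENARIOS = ("peaky", "orthogonal", "orthogonal_positive")


@dataclass
class SyntheticDataset:
    """A simulated observation matrix with its generating ground truth."""

    Y: ExpressionMatrix
    M_true: np.ndarray
    A_true: np.ndarray
    sigma2_true: float
    scenario: str
    snr_db: float
    seed: int
    n_clipped: int = 0


def generate_factors(
    scenario: str,
    G: int,
    R: int,
    rng,
    sparsity: float = 0.05,
    baseline: float = 1.0,
    peak: float = 10.0,
) -> np.ndarray:
    """Generate a G x R ground-truth factor matrix for one scenario.

    ``sparsity`` is the fraction of genes in each peaky factor's
    high-amplitude block; ``baseline``/``peak`` are the low/high amplitudes
    (arbitrary expression units) for the peaky and disjoint-support scenarios.
    """
    if R < 2 or G < R:
        raise ConfigError(f"need R >= 2 and G >= R, got G={G}, R={R}")
    if scenario == "peaky":
        block = max(1, int(np.ceil(sparsity * G)))
        if R * block > G:
            raise ConfigError(
                f"{R} disjoint blocks of {block} genes do not fit in G={G}"
            )
        order = rng.permutation(G)
        M = np.full((G, R), baseline)
        for r in range(R):
            M[order[r * block:(r + 1) * block], r] = peak
        return M
    if scenario == "orthogonal":
        X = rng.standard_normal((G, R))
        Q, _ = np.linalg.qr(X)
        # unit-mean-square entries so amplitudes are comparable across G
        return Q[:, :R] * np.sqrt(G)
    if scenario == "orthogonal_positive":
        block = G // R
        if block < 1:
            raise ConfigError(f"G={G} too small for {R} disjoint supports")
        order = rng.permutation(G)
        M = np.zeros((G, R))
        for r in range(R):
            idx = order[r * block:(r + 1) * block]
            M[idx, r] = peak * rng.uniform(0.5, 1.5, size=idx.size)
        return M
    raise ConfigError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")


def generate_scores(R: int, N: int, rng) -> np.ndarray:
    """R x N score matrix with columns drawn from a flat Dirichlet."""
    if R < 2:
        raise ConfigError("need R >= 2")
    return rng.dirichlet(np.ones(R), size=N).T


def mix_with_noise(M: np.ndarray, A: np.ndarray, snr_db: Optional[float], rng):
    """Mix Y = M A + noise at a target signal-to-noise ratio.

    The noise variance is chosen so that the average over samples of
    G^-1 sigma^-2 ||M a_i||^2 equals 10^(snr_db/10). ``snr_db=None`` (or
    +inf) returns the noise-free mixture. Negative entries produced by the
    Gaussian noise are clipped to zero (count returned and logged).

    Returns (Y, sigma2_true, n_clipped).
    """
    S = M @ A
    power = float(np.einsum("ij,ij->", S, S)) / S.size  # mean_i ||s_i||^2 / G
    if power == 0.0:
        raise ConfigError("all-zero mixture: signal-to-noise ratio undefined")
    if snr_db is None or np.isinf(snr_db):
        return S.copy(), 0.0, 0
    sigma2 = power / 10.0 ** (snr_db / 10.0)
    Y = S + np.sqrt(sigma2) * rng.standard_normal(S.shape)
    n_clipped = int(np.sum(Y < 0))
    if n_clipped:
        logger.info("clipped %d negative entries (%.3g%% of the matrix)",
                    n_clipped, 100.0 * n_clipped / Y.size)
        Y = np.clip(Y, 0.0, None)
    return Y, sigma2, n_clipped


def make_scenario(
    name: str,
    G: int = 512,
    N: int = 128,
    R: int = 3,
    snr_db: Optional[float] = 20.0,
    seed: int = 0,
    **factor_kwargs,
) -> SyntheticDataset:
    """Compose factors, scores, and noise into a full synthetic dataset."""
    if name not in SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(seed)
    M = generate_factors(name, G, R, rng, **factor_kwargs)
    A = generate_scores(R, N, rng)
    Y, sigma2, n_clipped = mix_with_noise(M, A, snr_db, rng)
    return SyntheticDataset(
        Y=ExpressionMatrix.from_values(Y),
        M_true=M,
        A_true=A,
        sigma2_true=sigma2,
        scenario=name,
        snr_db=np.inf if snr_db is None else float(snr_db),
        seed=int(seed),
        n_clipped=n_clipped,
    )
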
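"""Core container types: expression matrices, run configuration, factor models.

The observation model throughout the package is the linear mixing model

    Y = M A + N,

with ``Y`` a G x N matrix of non-negative expression values (G genes, N
samples), ``M`` a G x R matrix whose columns are non-negative gene signatures
("factors"), ``A`` an R x N matrix of factor scores whose columns live on the
probability simplex, and ``N`` i.i.d. Gaussian noise with variance sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError, ConstraintError

#: Valid settings for the constraint-ablation flag. "both" is the full model;
#: the other settings strip the positivity and/or sum-to-one constraint at run
#: time so their individual contribution can be measured.
CONSTRAINT_MODES = ("both", "positivity_only", "sum_to_one_only", "none")


def _has_positivity(mode: str) -> bool:
    return mode in ("both", "positivity_only")


def _has_sum_to_one(mode: str) -> bool:
    return mode in ("both", "sum_to_one_only")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of non-negative expression values.

    Parameters
    ----------
    values
        G x N array; entries must be finite and >= 0.
    gene_ids, sample_ids
        Unique row / column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConstraintError("expression values must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        g, n = self.values.shape
        if len(self.gene_ids) != g:
            raise ConstraintError(
                f"{len(self.gene_ids)} gene ids for {g} matrix rows"
            )
        if len(self.sample_ids) != n:
            raise ConstraintError(
                f"{len(self.sample_ids)} sample ids for {n} matrix columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConstraintError("expression values must all be finite")
        if np.any(self.values < 0):
            g_bad, s_bad = np.argwhere(self.values < 0)[0]
            raise ConstraintError(
                f"negative expression value at gene {self.gene_ids[g_bad]!r}, "
                f"sample {self.sample_ids[s_bad]!r}; non-negative input is required "
                "for the positivity interpretation of factors "
                "(constraint_mode=none applies to the fit, not to loading)"
            )
        if len(set(self.gene_ids)) != g:
            raise ConstraintError("duplicate gene_ids")
        if len(set(self.sample_ids)) != n:
            raise ConstraintError("duplicate sample_ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ExpressionMatrix":
        """Wrap a bare array with synthetic gene/sample identifiers."""
        values = np.asarray(values, dtype=np.float64)
        g, n = values.shape
        return cls(
            values,
            [f"gene_{i + 1:05d}" for i in range(g)],
            [f"sample_{j + 1:04d}" for j in range(n)],
        )


def as_expression_matrix(Y) -> ExpressionMatrix:
    """Coerce an array or ExpressionMatrix into an ExpressionMatrix."""
    if isinstance(Y, ExpressionMatrix):
        return Y
    return ExpressionMatrix.from_values(np.asarray(Y, dtype=np.float64))


@dataclass
class RunConfig:
    """Configuration of a Gibbs run.

    Parameters
    ----------
    r_max
        Upper bound on the number of factors; the factor-count prior is uniform
        on {2, ..., r_max}. Also fixes the working subspace dimension r_max - 1.
    n_mc, n_bi
        Total Monte Carlo iterations and burn-in length. Defaults mirror the
        settings used for the full-scale gene-chip analysis (10000 / 1000).
    s2
        Prior variance of the projected factor signatures (shared across
        factors).
    nu
        Shape hyperparameter of the inverse-Gamma noise-variance prior. With
        its scale hyperparameter marginalized under a Jeffreys prior, nu does
        not enter the sampled conditionals; it is kept configurable for
        completeness.
    move_probs
        (birth, death, switch) proposal probabilities; renormalized at the
        boundaries R = 2 (no death) and R = r_max (no birth).
    seed
        Seed of the single pseudo-random generator used by the whole run.
    constraint_mode
        One of ``both``, ``positivity_only``, ``sum_to_one_only``, ``none``.
    fixed_r
        If given, run in supervised mode at exactly this number of factors
        (no trans-dimensional moves).
    distinct_sad
        Minimal spectral angle (radians) a proposed signature must keep from
        every existing factor.
    proposal_max_tries
        Attempts at generating a feasible, distinct signature before a
        birth/switch proposal is abandoned.
    log_every
        Progress-log interval in iterations (0 disables logging).
    """

    r_max: int = 10
    n_mc: int = 10000
    n_bi: int = 1000
    s2: float = 50.0
    nu: float = 2.0
    move_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0
    constraint_mode: str = "both"
    fixed_r: Optional[int] = None
    distinct_sad: float = 0.05
    proposal_max_tries: int = 50
    feasibility_tol: float = 0.0
    sigma2_floor: float = 1e-12
    log_every: int = 0

    def __post_init__(self) -> None:
        if int(self.r_max) != self.r_max or self.r_max < 3:
            raise ConfigError("r_max must be an integer >= 3")
        self.r_max = int(self.r_max)
        if self.n_bi >= self.n_mc:
            raise ConfigError("burn-in n_bi must be smaller than n_mc")
        if self.n_mc <= 0:
            raise ConfigError("n_mc must be positive")
        if self.s2 <= 0:
            raise ConfigError("prior variance s2 must be positive")
        if self.nu <= 0:
            raise ConfigError("nu must be positive")
        probs = tuple(float(p) for p in self.move_probs)
        if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ConfigError("move_probs must be three non-negative values summing to 1")
        self.move_probs = probs
        if self.constraint_mode not in CONSTRAINT_MODES:
            raise ConfigError(
                f"constraint_mode must be one of {CONSTRAINT_MODES}, "
                f"got {self.constraint_mode!r}"
            )
        if self.fixed_r is not None:
            if not 2 <= int(self.fixed_r) <= self.r_max:
                raise ConfigError(
                    f"fixed_r={self.fixed_r} must satisfy 2 <= fixed_r <= r_max={self.r_max}"
                )
            self.fixed_r = int(self.fixed_r)

    @property
    def positivity(self) -> bool:
        return _has_positivity(self.constraint_mode)

    @property
    def sum_to_one(self) -> bool:
        return _has_sum_to_one(self.constraint_mode)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["move_probs"] = list(self.move_probs)
        return d


@dataclass
class FactorModel:
    """A full model state {M, A, sigma2} (R is implied by the shapes)."""

    M: np.ndarray
    A: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.M.ndim != 2 or self.A.ndim != 2:
            raise ConstraintError("M and A must be 2-D matrices")
        if self.M.shape[1] != self.A.shape[0]:
            raise ConstraintError(
                f"M has {self.M.shape[1]} factors but A has {self.A.shape[0]} rows"
            )
        self.sigma2 = float(self.sigma2)

    @property
    def R(self) -> int:
        return self.M.shape[1]

    def validate(
        self,
        constraint_mode: str = "both",
        r_max: Optional[int] = None,
        tol: float = 1e-10,
    ) -> None:
        """Raise :class:`ConstraintError` if an active constraint is violated."""
        if self.sigma2 <= 0:
            raise ConstraintError("sigma2 must be positive")
        if r_max is not None and not 2 <= self.R <= r_max:
            raise ConstraintError(f"R={self.R} outside [2, {r_max}]")
        if _has_positivity(constraint_mode):
            if self.M.min(initial=0.0) < -tol:
                raise ConstraintError("M has negative entries")
            if self.A.min(initial=0.0) < -tol:
                raise ConstraintError("A has negative entries")
        if _has_sum_to_one(constraint_mode):
            colsums = self.A.sum(axis=0)
            if np.max(np.abs(colsums - 1.0), initial=0.0) > tol:
                raise ConstraintError("columns of A do not sum to one")

    def satisfies(self, constraint_mode: str = "both", tol: float = 1e-10) -> bool:
        try:
            self.validate(constraint_mode=constraint_mode, tol=tol)
        except ConstraintError:
            return False
        return True
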
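"""Likelihood, priors, and the unnormalized log-posterior score.

The model pieces are:

* likelihood: Y | M, A, sigma2 ~ product of N(M a_i, sigma2 I_G);
* projected-factor prior: t_r ~ N(e_r, s2 I) truncated to the feasibility
  polyhedron (truncation normalization constants omitted -- they cancel in all
  within-dimension Gibbs ratios and are constant across states with equal R,
  which is the only regime in which posterior scores are compared);
* score prior: each column of A uniform on the simplex, density (R-1)!;
* factor count: R uniform on {2, ..., R_max};
* noise variance: inverse-Gamma(nu/2, gamma/2) with a Jeffreys prior on gamma;
  integrating gamma out analytically leaves the improper density 1/sigma2
  regardless of nu, which is the -log(sigma2) term of the posterior score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datamodel import FactorModel, as_expression_matrix
from .exceptions import ConstraintError
from .subspace import ProjectedBasis, in_feasible_set, project_factor


@dataclass
class PriorSpec:
    """Hyperparameters of the factor prior.

    Attributes
    ----------
    E
        (K-1) x R matrix of prior mean vectors e_r (one column per factor);
        each column must lie in the feasible set when positivity is active.
    s2
        Shared prior variance of the projected factors.
    nu
        Shape hyperparameter of the noise-variance prior (does not enter the
        sampled conditionals once its scale is marginalized; kept for
        completeness).
    R_max
        Support bound of the factor-count prior.
    """

    E: np.ndarray
    s2: float
    nu: float
    R_max: int


def ssr(Y, M: np.ndarray, A: np.ndarray) -> float:
    """Sum of squared residuals ||Y - M A||_F^2."""
    values = as_expression_matrix(Y).values
    resid = values - M @ A
    return float(np.einsum("ij,ij->", resid, resid))


def log_likelihood(Y, model: FactorModel) -> float:
    """Gaussian log-likelihood -(GN/2) log(2 pi sigma2) - SSR / (2 sigma2)."""
    values = as_expression_matrix(Y).values
    if model.sigma2 <= 0:
        raise ConstraintError("sigma2 must be positive")
    G, N = values.shape
    if model.M.shape[0] != G or model.A.shape[1] != N:
        raise ConstraintError(
            f"model shapes {model.M.shape} x {model.A.shape} do not match data {values.shape}"
        )
    ssr_val = ssr(values, model.M, model.A)
    return -(G * N / 2.0) * np.log(2.0 * np.pi * model.sigma2) - ssr_val / (
        2.0 * model.sigma2
    )


def log_prior_T(
    T: np.ndarray,
    prior: PriorSpec,
    basis: ProjectedBasis,
    tol: float = 0.0,
    check_feasible: bool = True,
) -> float:
    """Log of the truncated-Gaussian factor prior, up to its normalization.

    Returns -sum_r ||t_r - e_r||^2 / (2 s2) if every column back-projects to a
    non-negative signature, else -inf.
    """
    T = np.asarray(T, dtype=np.float64)
    if T.shape != prior.E.shape:
        raise ConstraintError(
            f"T has shape {T.shape} but prior means have shape {prior.E.shape}"
        )
    if check_feasible:
        for r in range(T.shape[1]):
            if not in_feasible_set(basis, T[:, r], tol=tol):
                return -np.inf
    diff = T - prior.E
    return -float(np.einsum("ij,ij->", diff, diff)) / (2.0 * prior.s2)


def log_prior_R(R: int, R_max: int) -> float:
    """Uniform prior on {2, ..., R_max}: -log(R_max - 1) on support, -inf off."""
    if 2 <= R <= R_max:
        return -float(np.log(R_max - 1))
    return -np.inf


def posterior_score_terms(
    ssr_val: float,
    sigma2: float,
    T: np.ndarray,
    E: np.ndarray,
    s2: float,
    R: int,
    R_max: int,
    G: int,
    N: int,
) -> float:
    """Shared core of the unnormalized log-posterior score.

    log-likelihood  - log(sigma2)  (marginalized noise-variance prior)
    - ||T - E||^2 / (2 s2)         (factor prior, truncation feasible)
    - log(R_max - 1)               (factor-count prior)
    + N log((R-1)!)                (uniform simplex score prior density)

    This same expression generates every Metropolis log-ratio used by the
    within-dimension sampler, guaranteeing one shared implementation.
    """
    ll = -(G * N / 2.0) * np.log(2.0 * np.pi * sigma2) - ssr_val / (2.0 * sigma2)
    diff = np.asarray(T) - np.asarray(E)
    lp_t = -float(np.einsum("ij,ij->", diff, diff)) / (2.0 * s2)
    return ll - np.log(sigma2) + lp_t + log_prior_R(R, R_max) + N * float(gammaln(R))


def log_posterior_score(
    Y,
    model: FactorModel,
    prior: PriorSpec,
    basis: ProjectedBasis,
    constraint_mode: str = "both",
    tol: float = 1e-9,
) -> float:
    """Unnormalized log-posterior of a full model state.

    Used for MAP ranking among stored samples with the same number of factors.
    Constraint violations return -inf rather than raising.
    """
    values = as_expression_matrix(Y).values
    G, N = values.shape
    if model.sigma2 <= 0:
        return -np.inf
    if not model.satisfies(constraint_mode, tol=tol):
        return -np.inf
    if not 2 <= model.R <= prior.R_max:
        return -np.inf
    T = np.column_stack(
        [project_factor(basis, model.M[:, r]) for r in range(model.R)]
    )
    if T.shape != prior.E.shape:
        return -np.inf
    ssr_val = ssr(values, model.M, model.A)
    return posterior_score_terms(
        ssr_val, model.sigma2, T, prior.E, prior.s2, model.R, prior.R_max, G, N
    )
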
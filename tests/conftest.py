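"""Shared fixtures: small deterministic datasets and fitted bases."""

import numpy as np
import pytest

from ublu.datamodel import ExpressionMatrix
from ublu.subspace import fit_projection


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix(rng):
    """A 12-gene x 8-sample non-negative matrix with a strong mean."""
    values = rng.uniform(1.0, 5.0, size=(12, 8))
    return ExpressionMatrix.from_values(values)


@pytest.fixture
def small_basis(small_matrix):
    return fit_projection(small_matrix, K=4)


@pytest.fixture
def rank3_mixture(rng):
    """Noise-free Y = M A with 3 non-negative factors and simplex scores."""
    G, N, R = 30, 16, 3
    M = rng.uniform(0.5, 2.0, size=(G, R))
    M[:5, 0] += 8.0
    M[5:10, 1] += 8.0
    M[10:15, 2] += 8.0
    A = rng.dirichlet(np.ones(R), size=N).T
    return M, A, ExpressionMatrix.from_values(M @ A)
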
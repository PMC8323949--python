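"""Shared fixtures: synthetic samples and mesenchymal matrices.

Expensive simulated samples are module-scoped (session scope keeps them alive
across test files) so the suite generates each condition once.
"""

import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from cafattract import (
    ExpressionMatrix,
    find_attractor,
    identify_mesenchymal,
    log_normalize,
    make_transition_spec,
)
from cafattract.synthetic import generate_sample, normal_profile, stage_profile

logging.getLogger("cafattract").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def spec():
    return make_transition_spec()


def mesenchymal_matrix(spec, profile, seed):
    """Generate, normalize and subset to called mesenchymal cells."""
    matrix, truth = generate_sample(spec, profile, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normed = log_normalize(matrix)
    calls = identify_mesenchymal(normed)
    keep = [c.cell for c in calls if c.call in ("fibroblast", "pericyte")]
    return normed.subset_cells(keep), truth


@pytest.fixture(scope="session")
def normal_sample(spec):
    """A normal-like sample (t ~ 0): full matrix plus ground truth."""
    matrix, truth = generate_sample(spec, normal_profile("N1"), seed=11)
    return matrix, truth


@pytest.fixture(scope="session")
def normal_mesenchymal(spec):
    return mesenchymal_matrix(spec, normal_profile("N1"), seed=11)[0]


@pytest.fixture(scope="session")
def caf_rich_mesenchymal(spec):
    return mesenchymal_matrix(spec, stage_profile("T9", 0.95), seed=21)[0]


@pytest.fixture(scope="session")
def normal_attractor(normal_mesenchymal):
    return find_attractor(normal_mesenchymal, "LUM")


def dense_matrix(rng, n_genes=40, n_cells=120, prefix="G"):
    """Small random NB count matrix for IO / DE tests."""
    mu = rng.uniform(1, 20, n_genes)[:, None]
    counts = rng.poisson(rng.gamma(1 / 0.3, mu * 0.3, (n_genes, n_cells)))
    return ExpressionMatrix(
        counts=counts,
        genes=pd.Index([f"{prefix}{i:03d}" for i in range(n_genes)]),
        cells=pd.Index([f"c{i:03d}" for i in range(n_cells)]),
        sample="rand",
    )


@pytest.fixture
def random_matrix():
    return dense_matrix(np.random.default_rng(7))
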
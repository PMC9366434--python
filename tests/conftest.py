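"""Shared fixtures: a small IS library and a small simulated genome.

The small genome (200 kbp, 3 IS groups, 3 clusters) keeps per-test
detection runs fast; study-scale (1 Mbp) simulations run only in the
acceptance suite.
"""

import numpy as np
import pytest

from cyanoarch.is_catalog import classify_copies, find_is_copies, group_is_copies
from cyanoarch.synthetic_data import (
    ClusterSpec,
    ISGroupSpec,
    SimulationConfig,
    build_is_library,
    simulate_genome,
)


def small_config(seed: int, divergence: float = 0.02) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        chromosome_length=200_000,
        is_groups=[
            ISGroupSpec("group_1", n_full=4, n_fragment=2, divergence=divergence),
            ISGroupSpec("group_2", n_full=3, n_fragment=2, divergence=divergence),
            ISGroupSpec("group_3", n_full=2, n_fragment=1, divergence=divergence),
        ],
        clusters=[
            ClusterSpec("mvd", n_genes=6, gene_length=800),
            ClusterSpec("apn", n_genes=5, gene_length=2400),
            ClusterSpec("oci", n_genes=4, gene_length=3500),
        ],
        anchor_spacing=10_000,
    )


@pytest.fixture(scope="session")
def library():
    return build_is_library(n_groups=3, seed=7)


@pytest.fixture(scope="session")
def small_sim(library):
    """(replicons, truth) for the small seeded genome."""
    return simulate_genome(small_config(seed=11), library)


@pytest.fixture(scope="session")
def cataloged(library, small_sim):
    """Detected, grouped, and classified IS copies of the small genome."""
    replicons, _ = small_sim
    copies = find_is_copies(replicons[0], library)
    copies = group_is_copies(copies, library=library)
    return classify_copies(copies, library)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_922)
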
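"""Shared fixtures.

``small_community`` is a fast desk-scale community (short ancestors) used
by most integration tests; ``default_community_result`` runs the full
default-scale community once per session (ANI + both clusterings) and is
shared by the recovery / refinement / superinfection acceptance checks.
"""

import numpy as np
import pytest

from paraphage import cluster as cl
from paraphage.ani import AniParams, compute_ani_matrix
from paraphage.synth import SimConfig, generate_community


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_species=10,
        fraction_singletons=0.5,
        cosmopolitan_sizes=(6,),
        cosmopolitan_st_spread=(3,),
        mid_size_range=(2, 4),
        ancestor_length_range=(6_000, 9_000),
        n_genomes=30,
        n_sts=5,
        n_countries=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_community):
    return compute_ani_matrix(small_community.sequences)


@pytest.fixture(scope="session")
def small_partition(small_matrix):
    graph = cl.build_graph(small_matrix)
    return cl.name_species(cl.paraclique_partition(graph))


@pytest.fixture(scope="session")
def default_community_result():
    """Default-scale community run end-to-end: matrix + strict/lenient partitions."""
    community = generate_community(SimConfig(seed=1))
    matrix = compute_ani_matrix(community.sequences)
    strict_params = cl.ClusterParams()
    strict = cl.name_species(
        cl.paraclique_partition(cl.build_graph(matrix, strict_params), 0.9,
                                params=strict_params)
    )
    lenient_params = cl.ClusterParams(min_identity=70.0, min_coverage=70.0)
    lenient = cl.name_species(
        cl.paraclique_partition(cl.build_graph(matrix, lenient_params), 0.9,
                                params=lenient_params)
    )
    return community, matrix, strict, lenient


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
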
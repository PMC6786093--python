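import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mdcap import (
    AssociationRecord,
    BipartiteNetwork,
    DiseaseOntology,
    MDCAPConfig,
    SyntheticSpec,
    generate_network,
)
from mdcap.synthetic import disease_blocks, generate_ontology

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def chain_ontology():
    """Two sibling diseases under one parent: C01.01 and C01.02 under C01."""
    return DiseaseOntology(
        {
            "heart attack": {"C01.01"},
            "stroke": {"C01.02"},
            "root disease": {"C01"},
            "far disease": {"D05.10"},
        }
    )


@pytest.fixture
def toy_records():
    mk = AssociationRecord
    return [
        mk("hsa-mir-1", "heart attack", "Target", 1, True),
        mk("hsa-mir-1", "stroke", "Target", 2, True),
        mk("hsa-mir-2", "stroke", "Genetics", 3, True),
        mk("hsa-mir-2", "far disease", "Epigenetics", 4, False),
    ]


@pytest.fixture
def toy_network(toy_records):
    """2 miRNAs x 3 diseases causal network: {(m1,d1),(m1,d2),(m2,d2)}."""
    from mdcap import build_network

    return build_network(toy_records, causal_only=True)


@pytest.fixture(scope="session")
def planted():
    """Default planted-block network with a block-informative ontology."""
    spec = SyntheticSpec(seed=7)
    with pytest.warns(UserWarning):
        net, records = generate_network(spec)
    ontology = generate_ontology(net.diseases, disease_blocks(net, spec), seed=7)
    return spec, net, records, ontology


def random_network(rng: np.random.Generator, n_m=5, n_d=6) -> BipartiteNetwork:
    """A random small bipartite network with no empty row or column."""
    while True:
        adj = (rng.random((n_m, n_d)) < 0.4).astype(float)
        if adj.sum(axis=0).all() and adj.sum(axis=1).all():
            break
    return BipartiteNetwork(
        [f"hsa-mir-{i}" for i in range(n_m)],
        [f"disease {j}" for j in range(n_d)],
        adj,
    )


@pytest.fixture
def default_config():
    return MDCAPConfig()
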
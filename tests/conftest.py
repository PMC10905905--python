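import numpy as np
import pytest

from moldescpred import FeatureSchema, GINConfig, featurize_molecule


@pytest.fixture(scope="session")
def schema():
    return FeatureSchema()


@pytest.fixture(scope="session")
def tiny_gin_config(schema):
    """Reduced-width encoder config used for fast unit tests."""
    return GINConfig(
        node_feature_dim=schema.node_feature_dim,
        edge_feature_dim=schema.edge_feature_dim,
        num_layers=3,
        hidden_dim=16,
        representation_dim=24,
        dropout_rate=0.1,
    )


@pytest.fixture(scope="session")
def small_molecules():
    return ["C", "CC", "CCO", "c1ccccc1", "CC(=O)O", "c1ccncc1", "CCN(CC)CC",
            "C1CCCCC1", "CCOC", "CC#N", "c1ccc(Cl)cc1", "CCS", "OCC(O)CO",
            "c1ccc(Br)cc1C", "CC(C)C", "C1CCOC1", "NCCO", "CCCCCC", "c1ccoc1",
            "CC(=O)NC"]


@pytest.fixture(scope="session")
def small_graphs(small_molecules, schema):
    return [featurize_molecule(s, schema) for s in small_molecules]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
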
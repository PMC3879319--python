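import numpy as np
import pytest
from hypothesis import settings

from luminet.mlp_core import TrainingConfig, make_mccv_splits, scale_to_unit
from luminet.synthetic_data import ExpressionConfig, generate_expression

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-epoch trainer settings for quick, still-converging runs."""
    return TrainingConfig(max_epochs=100, patience_epochs=50, seed=0)


@pytest.fixture(scope="session")
def planted_dataset():
    """100 probes x 200 samples, 5 strongly informative probes, 20-probe DAG panel."""
    cfg = ExpressionConfig(
        n_probes=100,
        n_samples=200,
        n_class1=118,
        n_informative=5,
        effect_size=2.0,
        panel_size=20,
        n_planted_edges=10,
        edge_coefficient_range=(0.5, 1.0),
        noise_sd=0.3,
        seed=1,
    )
    dataset, truth = generate_expression(cfg)
    return dataset, truth, cfg


@pytest.fixture(scope="session")
def scaled_planted(planted_dataset):
    dataset, truth, cfg = planted_dataset
    return scale_to_unit(dataset), truth, cfg


@pytest.fixture(scope="session")
def one_split():
    return make_mccv_splits(200, 1, seed=0)[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
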
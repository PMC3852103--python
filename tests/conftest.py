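import numpy as np
import pytest

from mirout import SimulationConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A small but fully structured 4-dataset scenario with strong signal."""
    cfg = SimulationConfig(
        n_normal=10,
        n_tumor=20,
        n_features=120,
        de_fraction=0.05,
        outlier_fraction=0.3,
        shift=3.0,
        n_genes=600,
        n_signal_genes=60,
        n_gene_sets=12,
        n_true_gene_sets=3,
        gene_set_size=25,
        seed=11,
    )
    datasets, truths, target_map, collection = generate_scenario(cfg)
    return cfg, datasets, truths, target_map, collection


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
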
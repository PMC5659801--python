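import numpy as np
import pytest

from eportraffic.model import ModelVariant, CellParameters
from eportraffic.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def acd() -> ModelVariant:
    return ModelVariant.from_name("ACD")


@pytest.fixture(scope="session")
def median_params(acd) -> CellParameters:
    """Kinetic parameters at the generator's log-medians (ACD variant)."""
    cfg = GeneratorConfig()
    values = {"k_on": cfg.k_on, "k_off": cfg.k_off}
    values.update({p: 10.0 ** cfg.log10_means[p] for p in acd.cell_param_names})
    return CellParameters.for_variant(acd, values)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three cells (one per condition) with default noise, seed 3."""
    cfg = GeneratorConfig(n_epo_cells=1, n_bleach_cells=1, n_chx_cells=1)
    table, truth = generate_dataset(cfg, 3)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_dataset():
    """Four epo + two bleach + two chx cells, seed 11."""
    cfg = GeneratorConfig(n_epo_cells=4, n_bleach_cells=2, n_chx_cells=2)
    table, truth = generate_dataset(cfg, 11)
    return cfg, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
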
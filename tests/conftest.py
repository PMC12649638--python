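import numpy as np
import pandas as pd
import pytest

from polypnet import synthetic_data as sim


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_sim():
    """A small 3-module factor-model dataset with moderate noise."""
    cfg = sim.SimConfig(
        n_genes=240,
        module_sizes=(80, 70, 50),
        n_per_group=5,
        loading_range=(0.7, 0.9),
        trait_effect=2.0,
        driven_module_index=1,
        seed=11,
    )
    expr, groups, truth = sim.simulate_expression(cfg)
    return cfg, expr, groups, truth


@pytest.fixture
def zero_noise_two_modules():
    """Two perfectly coherent planted modules (loadings 1, no noise)."""
    cfg = sim.SimConfig(
        n_genes=80,
        module_sizes=(45, 35),
        n_per_group=5,
        loading_range=(1.0, 1.0),
        noise_sd=0.0,
        trait_effect=0.0,
        driven_module_index=0,
        seed=3,
    )
    expr, groups, truth = sim.simulate_expression(cfg)
    return expr, groups, truth


@pytest.fixture
def physio_table():
    cfg = sim.SimConfig(n_genes=10, module_sizes=(4,), n_per_group=5, seed=7)
    return sim.simulate_physiology(cfg)


def make_expression(values, samples=None):
    """Wrap a 2-D array as an expression DataFrame with default ids."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if samples is None:
        samples = sim.sample_names(n_samples // 2)
    return pd.DataFrame(
        values,
        index=[f"g{i + 1}" for i in range(n_genes)],
        columns=samples,
    )
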
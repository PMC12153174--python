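"""Shared fixtures: a scaled-down synthetic system for fast unit tests and
one near-study-size pipeline reused by the slower end-to-end checks."""

import numpy as np
import pytest

from allomprop.synthdata import (
    GeneratorConfig,
    generate_fitting_data,
    generate_inventory,
)
from allomprop.system import AllometricSystem


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Reduced sample sizes for fast fitting; same noise structure."""
    return GeneratorConfig(
        seed=101,
        sample_sizes={
            "TSV_IB": 400, "TSV_BK": 380, "TSV_OB": 450,
            "B_BK": 180, "B_BR": 160, "B_AG": 150,
        },
        profile_obs={"R_IB": 3000, "R_OB": 3400},
        pool_size=900,
        n_plots=260,
        target_trees=220,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_fitting_data(small_cfg)


@pytest.fixture(scope="session")
def small_inventory(small_cfg):
    return generate_inventory(small_cfg)


@pytest.fixture(scope="session")
def small_fit(small_data):
    return AllometricSystem(small_data).fit(n_boot=60, seed=11)


@pytest.fixture(scope="session")
def default_pipeline():
    """Study-condition pipeline: default generator, moderate bootstrap and
    replicate counts. Shared by the end-to-end pattern checks."""
    cfg = GeneratorConfig(seed=7)
    data = generate_fitting_data(cfg)
    inventory = generate_inventory(cfg)
    fit = AllometricSystem(data).fit(n_boot=300, seed=7)
    results = fit.propagate(inventory, n_replicates=300, seed=7)
    return cfg, data, inventory, fit, results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
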
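import logging

import numpy as np
import pytest

from oculoeffort import (
    EffectParams,
    PipelineConfig,
    SimulationConfig,
    TaskSpec,
    default_geometry,
    generate_dataset,
)

logging.getLogger("oculoeffort").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated experiment shared by structural tests."""
    cfg = SimulationConfig(
        n_participants_per_condition={"neutral": 2, "aversive": 2, "erotic": 2},
        task=TaskSpec(n_trials=6, n_training=2),
        seed=7,
    )
    ds, truth = generate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def default_pipeline_config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
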
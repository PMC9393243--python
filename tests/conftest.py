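import copy

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tdlymph.synth import CohortConfig, default_config

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cfg() -> CohortConfig:
    """Packaged study-condition defaults."""
    return default_config()


@pytest.fixture()
def cfg_dict(cfg) -> dict:
    """Mutable copy of the default configuration dictionary."""
    return copy.deepcopy(cfg.raw)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220808)
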
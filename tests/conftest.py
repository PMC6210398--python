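import logging
import warnings

import numpy as np
import pytest

from boundless import validation
from boundless.sensors import fibonacci_cap_array
from boundless.simulate import reduced_config, simulate_recording

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore", message="fewer epochs than channels")


@pytest.fixture(scope="session")
def small_sensors():
    """24 point magnetometers on a 12-cm shell (9-cm conductor sphere)."""
    return fibonacci_cap_array(24, 0.12)


@pytest.fixture(scope="session")
def tiny_sim():
    """One small graded recording + truth, shared across tests."""
    cfg = reduced_config(seed=7, n_channels=24, condition_len=12.0, rest_len=12.0)
    rec, truth = simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def analysis_cfg():
    return validation.reduced_analysis_config()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
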
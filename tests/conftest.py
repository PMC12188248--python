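import numpy as np
import pytest

from flyssvep import SimConfig, simulate_recording
from flyssvep.preprocess import preprocess


def fast_config(**kw) -> SimConfig:
    """Simulator defaults at the 200 Hz analysis rate (overnight-recording rate)."""
    return SimConfig(fs=200.0, **kw)


@pytest.fixture(scope="session")
def phasic_recording():
    """A ~7.7 min phasic-oddball recording shared by read-only tests."""
    return simulate_recording(fast_config(), 20 * 23.0, "phasic", seed=11)


@pytest.fixture(scope="session")
def preprocessed(phasic_recording):
    rec, cmap, report = preprocess(_copy(phasic_recording))
    return rec, cmap, report


@pytest.fixture()
def noise_free_recording():
    cfg = fast_config()
    cfg.noise.pink_sd = 0.0
    cfg.noise.line_amp = 0.0
    return simulate_recording(cfg, 120.0, "phasic", seed=7)


def _copy(rec):
    import copy

    return copy.deepcopy(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
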
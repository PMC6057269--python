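import numpy as np
import pytest

from cmequant import synth


@pytest.fixture
def noiseless_config():
    """Small movie configuration with both noise sources disabled."""
    return synth.ImagingConfig(
        n_frames=40,
        height_px=48,
        width_px=48,
        photon_scale=0.0,
        read_noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_event(**overrides) -> synth.EventSpec:
    defaults = dict(
        event_id=0,
        x_px=24.0,
        y_px=24.0,
        t_start_s=5.0,
        lifetime_s=20.0,
        amplitudes=(500.0, 500.0),
        rise_tau_s=1.0,
        fall_tau_s=1.0,
    )
    defaults.update(overrides)
    return synth.EventSpec(**defaults)
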
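from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gazescan as gs

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def short_params():
    """Quiet, short session parameters for fast deterministic tests."""
    return replace(
        gs.default_params("optimal", "lower"),
        duration_s=60.0,
        n_trials=2,
        seed=42,
    )


@pytest.fixture
def noise_free_params(short_params):
    """Short session with every stochastic amplitude switched off."""
    return replace(
        short_params,
        noise_sd_eye=0.0,
        noise_sd_head=0.0,
        head_sway_sd=0.0,
        head_recruit_sd=0.0,
        fixation_jitter_sd=0.0,
    )


@pytest.fixture
def short_session(short_params):
    return gs.simulate_session(short_params)


def make_trace(effector, frame, yaw, pitch, rate=120.0, valid=None):
    yaw = np.asarray(yaw, dtype=float)
    t = np.arange(yaw.size) / rate
    return gs.EffectorTrace(
        effector, frame, t, yaw, np.asarray(pitch, dtype=float), valid=valid,
        nominal_rate=rate,
    )
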
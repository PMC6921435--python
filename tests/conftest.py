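import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecgdelta as e

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_config() -> e.SessionConfig:
    """Two minutes at 500 Hz: enough beats for delineation checks, fast."""
    return e.SessionConfig(duration_s=120.0, random_seed=11)


@pytest.fixture(scope="session")
def clean_config() -> e.SessionConfig:
    """Noise-free variant of the short session."""
    return e.SessionConfig(duration_s=120.0, random_seed=11, noise_sd_mV=0.0)


@pytest.fixture(scope="session")
def clean_pair(clean_config):
    """Noise-free rendered (G, NG) pair under the default effect profile."""
    return e.generate_session_pair(clean_config, e.GlucoseEffectProfile(),
                                   participant_seed=42, render_trace=True)


@pytest.fixture(scope="session")
def null_pair(clean_config):
    """Noise-free rendered pair with every effect gain at 1."""
    return e.generate_session_pair(clean_config, e.GlucoseEffectProfile.null(),
                                   participant_seed=42, render_trace=True)


def match_beats(detected_r: np.ndarray, truth: e.GroundTruth) -> np.ndarray:
    """Index of the ground-truth beat nearest each detected R peak."""
    gt_r = truth.fiducials["R"]
    return np.array([int(np.argmin(np.abs(gt_r - r))) for r in detected_r])
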
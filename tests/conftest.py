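import numpy as np
import pytest

from spatbeat import CohortConfig, RampProtocol


@pytest.fixture
def default_protocol():
    return RampProtocol.default_ramp()


@pytest.fixture
def noise_free_config():
    """Deterministic cohort: no between-spat spread, no jitter, no arrest."""
    return CohortConfig(
        hr_intercept_22c={"Ta10": 80.0, "Ta22": 80.0},
        hr_slope_cooling={"Ta10": 5.0, "Ta22": 5.0},
        intercept_sd=0.0,
        arrest_threshold_mean={"Ta10": -1000.0, "Ta22": -1000.0},
        arrest_threshold_sd={"Ta10": 0.0, "Ta22": 0.0},
        ibi_jitter_sd_at_22c=0.0,
        ibi_jitter_growth=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
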
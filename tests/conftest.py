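import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def sinusoid_beats(base_ms=800.0, amp_ms=40.0, freq_hz=0.25, duration_s=66.0,
                   t0_s=0.0, noise_ms=0.0, seed=0):
    """IBI series with sinusoidal respiratory modulation (analytic test signal)."""
    rng = np.random.default_rng(seed)
    t = t0_s
    ibis = []
    while t < t0_s + duration_s:
        ibi = base_ms + amp_ms * math.sin(2 * math.pi * freq_hz * (t - t0_s))
        if noise_ms:
            ibi += noise_ms * rng.normal()
        ibis.append(ibi)
        t += ibi / 1000.0
    from dyadsync.ibi import BeatSeries

    return BeatSeries(np.asarray(ibis), t0_s=t0_s)


@pytest.fixture
def small_config():
    from dyadsync.config import SimConfig

    return SimConfig(n_dyads=12, seed=123)
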
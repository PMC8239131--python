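import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hrvconcord as hc

settings.register_profile(
    "suite",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def constant_series():
    """10 minutes of perfectly regular 800 ms beats."""
    return hc.BeatSeries.from_bbis([800.0] * 750, recording_id="constant")


@pytest.fixture
def quiet_config():
    """Generator config with no artifacts, short duration, default dynamics."""
    return hc.SyntheticConfig(
        duration_h=0.5, ectopic_rate_per_h=0.0, outlier_rate_per_h=0.0, seed=7
    )


def pure_tone_series(freq_hz: float, amp_ms: float, duration_h: float = 0.2,
                     jitter_sd_ms: float = 0.0, seed: int = 0) -> hc.BeatSeries:
    """A recording whose only BBI modulation is one fixed-amplitude sinusoid."""
    hf_amp = amp_ms if freq_hz >= 0.15 else 0.0
    lf_amp = amp_ms if freq_hz < 0.15 else 0.0
    cfg = hc.SyntheticConfig(
        duration_h=duration_h,
        base_bbi_ms=850.0,
        hf=hc.Oscillation(freq_hz if hf_amp else 0.25, hf_amp, 1e6, 0.0),
        lf=hc.Oscillation(freq_hz if lf_amp else 0.10, lf_amp, 1e6, 0.0),
        slow_trend=hc.SlowTrend(0.0, 3600.0),
        jitter_sd_ms=jitter_sd_ms,
        ectopic_rate_per_h=0.0,
        outlier_rate_per_h=0.0,
        seed=seed,
    )
    return hc.generate_recording(cfg)


def brute_force_rmssd(bbis) -> float:
    d = [bbis[i + 1] - bbis[i] for i in range(len(bbis) - 1)]
    return float(np.sqrt(sum(x * x for x in d) / len(d)))


def brute_force_sdnn(bbis) -> float:
    n = len(bbis)
    mean = sum(bbis) / n
    return float(np.sqrt(sum((b - mean) ** 2 for b in bbis) / (n - 1)))
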
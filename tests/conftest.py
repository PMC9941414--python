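import time

import numpy as np
import pytest
from hypothesis import settings

from scopeflow.simulator import ScanConfig, VirtualSample, acquire_stack, make_sample

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

FAST_POLL = 0.05


def wait_until(predicate, timeout=10.0, interval=0.01, message="condition"):
    """Poll a predicate until true; fail the test on timeout."""
    deadline = time.monotonic() + timeout
    while time.monotonic() < deadline:
        if predicate():
            return
        time.sleep(interval)
    pytest.fail(f"timed out after {timeout}s waiting for {message}")


@pytest.fixture
def small_scan():
    """8×8-step scan, pitch == steps, noiseless: exactly invertible."""
    return ScanConfig(steps_per_axis=8, foci_pitch_px=8, frame_period_ms=1.0)


@pytest.fixture
def spots_sample():
    return make_sample("spots", 96, seed=7)


@pytest.fixture
def small_stack(spots_sample, small_scan):
    return acquire_stack(spots_sample, (0.0, 0.0), small_scan, fov_px=(32, 32))


def random_sample(seed: int, size: int = 64) -> VirtualSample:
    """Integer-valued random specimen (uniform photon counts)."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 1000, size=(size, size)).astype(np.float64)
    return VirtualSample(image=img, seed=seed)
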
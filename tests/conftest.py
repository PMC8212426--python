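import numpy as np
import pytest

from saccadekit import (
    add_noise,
    random_scanpath_spec,
    synthesize_scanpath,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def five_saccade_truth():
    """Noise-free 500 Hz recording with five 10-deg normal saccades."""
    from saccadekit.simulate import SaccadeParams, ScanpathSpec

    spec = ScanpathSpec(
        sampling_rate=500.0,
        saccades=[SaccadeParams(eta=550.0, c=6.0, A=10.0)] * 5,
        signs=[1, -1, 1, -1, 1],
        fixation_durations=[0.5] * 6,
        seed=7,
    )
    return synthesize_scanpath(spec)


@pytest.fixture(scope="session")
def random_recording():
    """Randomized 10-saccade recording (clean series + truth + noisy copy)."""
    spec = random_scanpath_spec(10, sampling_rate=500.0, seed=21)
    clean, truth = synthesize_scanpath(spec)
    noisy = add_noise(clean, 0.4, seed=22)
    return clean, truth, noisy
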
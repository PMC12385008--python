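import numpy as np
import pytest

from eegstress.data import MultiChannelRecording, SynthSpec, generate_synthetic_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trialset():
    """Ten trials per class, 6 channels, 5 s at 128 Hz (fast to process)."""
    spec = SynthSpec(
        n_trials_per_class=10,
        n_channels=6,
        duration_s=5.0,
        informative_channels=(0, 1, 2),
        seed=7,
    )
    return generate_synthetic_dataset(spec)


@pytest.fixture()
def sine_recording():
    """Two channels: 8 Hz and 10 Hz unit sines, 8 s at 128 Hz."""
    fs = 128.0
    t = np.arange(int(8 * fs)) / fs
    data = np.stack([np.sin(2 * np.pi * 8 * t), np.sin(2 * np.pi * 10 * t)])
    return MultiChannelRecording(data, fs)
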
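import numpy as np
import pytest

from neurocouple import MultichannelRecording, generate_montage


@pytest.fixture(scope="session")
def geometry():
    return generate_montage(n_fnirs=6, head_radius=85.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=500.0, modality="EEG", labels=None, **kw):
    data = np.asarray(data)
    labels = labels or [f"ch{i}" for i in range(data.shape[1])]
    return MultichannelRecording(
        data=data, fs=fs, channel_labels=labels, modality=modality, **kw
    )


@pytest.fixture()
def sinusoid_recording():
    """10 Hz unit sinusoid, 30 s at 500 Hz, one channel."""
    t = np.arange(0, 30, 1 / 500.0)
    return make_recording(np.sin(2 * np.pi * 10 * t)[:, None])
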
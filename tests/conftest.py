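import numpy as np
import pytest

from emgstim import EmgRecording, SimConfig, generate_emg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """2-channel, 2 s random recording at 1 kHz with mixed labels."""
    samples = rng.standard_normal((2, 2000)) * 10.0
    labels = np.full(2000, -1)
    labels[500:1500] = 3
    return EmgRecording(samples=samples, sampling_rate=1000.0, posture_labels=labels)


@pytest.fixture
def posture_recording():
    """Synthetic recording with one strongly active and one silent channel."""
    act = np.zeros((2, 4))
    act[0, :] = 50.0
    cfg = SimConfig(
        activation_matrix=act,
        posture_sequence=[(p, 2.0) for p in range(4)],
        baseline_noise=1.0,
        seed=7,
    )
    rec, gt = generate_emg(cfg)
    return rec, gt
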
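import numpy as np
import pytest

from eegqc import QCConfig, epoch, highpass
from eegqc.simulate import SyntheticSpec, generate_recording


@pytest.fixture(scope="session")
def cfg():
    return QCConfig()


@pytest.fixture(scope="session")
def clean_recording():
    """60 s clean synthetic recording (16 ch, 256 Hz, 10 Hz alpha)."""
    rec, truth = generate_recording(SyntheticSpec(duration_s=60.0, seed=123))
    return rec


@pytest.fixture(scope="session")
def clean_filtered(clean_recording, cfg):
    return highpass(clean_recording, cfg.highpass_hz)


@pytest.fixture(scope="session")
def clean_epochs(clean_filtered, cfg):
    return epoch(clean_filtered, cfg.epoch_len_s)


def toy_recording(seed, n_channels=4, n_epochs=8, fs=256.0, epoch_len_s=2.0,
                  inject=True):
    """Small correlated recording for oracle-equivalence checks; with
    ``inject`` it randomly amplifies a channel and/or adds an epoch
    burst so the flagging paths are actually exercised."""
    from eegqc.recording_io import Recording

    rng = np.random.default_rng(seed)
    s = int(epoch_len_s * fs)
    t = n_epochs * s
    common = rng.standard_normal(t)
    data = (common[None, :] * rng.uniform(0.7, 1.3, size=(n_channels, 1))
            + 0.6 * rng.standard_normal((n_channels, t)))
    if inject:
        if rng.random() < 0.5:
            data[rng.integers(n_channels)] *= rng.uniform(3, 10)
        if rng.random() < 0.5:
            e = rng.integers(n_epochs)
            c = rng.integers(n_channels)
            data[c, e * s:(e + 1) * s] += rng.uniform(10, 30) * np.hanning(s)
    labels = [f"CH{i}" for i in range(n_channels)]
    return Recording(data=data, fs=fs, labels=labels, condition="EC")
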
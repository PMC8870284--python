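import numpy as np
import pytest

from eeggraph import CohortConfig, EEGRecording
from eeggraph.connectivity import Network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast cohort: 3 subjects per group, short recordings."""
    return CohortConfig(
        n_per_group=3,
        duration_s=46.0,
        wm_duration_s=46.0,
        states=("eyes_open",),
        seed=321,
    )


@pytest.fixture
def sine_recording():
    """Two-channel recording holding pure 10 Hz and 60 Hz tones."""
    fs = 250.0
    t = np.arange(int(10 * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 60 * t)])
    return EEGRecording(
        data=data,
        fs=fs,
        channel_labels=("S10", "S60"),
        subject_id="sine",
        group="middle_aged",
        state="eyes_open",
    )


def binary_network(adj: np.ndarray) -> Network:
    return Network(w=np.asarray(adj, float), density=1.0, mode="binary")


def weighted_network(w: np.ndarray) -> Network:
    return Network(w=np.asarray(w, float), density=1.0, mode="weighted")


@pytest.fixture
def path3():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return binary_network(a)


@pytest.fixture
def star5():
    a = np.zeros((5, 5))
    a[0, 1:] = a[1:, 0] = 1
    return binary_network(a)


@pytest.fixture
def k4():
    a = np.ones((4, 4)) - np.eye(4)
    return binary_network(a)
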
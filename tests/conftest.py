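import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eegfc as E

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_noise_recording(seed=0, n_channels=8, fs=256.0, duration_s=160.0,
                         group="pos", condition="EO", subject_id="s01"):
    """A plain white-noise recording (cheapest valid EegRecording)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    labels = E.CANONICAL_CHANNELS[:n_channels] if n_channels <= 8 else tuple(
        f"ch{i}" for i in range(n_channels))
    return E.EegRecording(subject_id=subject_id, condition=condition,
                          group=group,
                          data=rng.standard_normal((n_channels, n)),
                          fs=fs, channel_labels=labels)


def random_ps_matrix(seed, n=8, index="PLV", band="alpha", condition="EO",
                     subject_id="s01"):
    """A random valid connectivity matrix (symmetric, [0,1], unit diagonal)."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.05, 0.95, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return E.ConnectivityMatrix(values=a, index=index, band=band,
                                condition=condition, subject_id=subject_id,
                                channel_labels=E.CANONICAL_CHANNELS[:n])


def full_matrix_set(subject_id, group_seed, n=8):
    """All 20 matrices (2 indices x 2 conditions x 5 bands) for one subject."""
    mats = []
    s = group_seed
    for condition in E.CONDITIONS:
        for index in ("PLV", "PLI"):
            for band in E.BAND_NAMES:
                mats.append(random_ps_matrix(s, n=n, index=index, band=band,
                                             condition=condition,
                                             subject_id=subject_id))
                s += 1
    return mats


@pytest.fixture
def matrix_set():
    return full_matrix_set


@pytest.fixture
def noise_recording():
    return make_noise_recording()
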
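import warnings

import numpy as np
import pytest
from hypothesis import settings

import ernstates as es

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage30():
    return es.make_montage(30)


@pytest.fixture(scope="session")
def montage12():
    return es.make_montage(12)


@pytest.fixture(scope="session")
def maps4(montage30):
    return es.make_ground_truth_maps(4, montage30, seed=1)


@pytest.fixture(scope="session")
def resting_rec(maps4, montage30):
    """120 s resting recording at 250 Hz, snr 5, mean dwell 80 ms."""
    rec, truth = es.simulate_resting_recording(
        maps4, montage30, duration_s=120.0, rate=250.0, mean_segment_ms=80.0, snr=5.0, seed=7
    )
    return rec, truth


@pytest.fixture(autouse=True)
def _no_warning_noise():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def rand_recording(montage, n_samples, rate=250.0, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((montage.n_channels, n_samples))
    return es.EEGRecording(es.average_reference(data), rate, montage)
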
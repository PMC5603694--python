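import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from affectmvpc import synthetic
from affectmvpc.datasets import VolumeGeometry
from affectmvpc.labels import binarize_labels

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry() -> VolumeGeometry:
    return VolumeGeometry((6, 6, 6))


@pytest.fixture(scope="session")
def stimulus_set():
    return synthetic.generate_stimulus_set(n_stim=24, seed=7)


@pytest.fixture(scope="session")
def stimulus_labels(stimulus_set):
    return binarize_labels(stimulus_set)


@pytest.fixture(scope="session")
def small_null_dataset(stimulus_set, small_geometry):
    """6 subjects x 12 stimuli of label-free (snr = 0) betas."""
    enc = synthetic.random_encoding_spec(small_geometry, snr=0.0, seed=5)
    return synthetic.generate_subject_betas(
        stimulus_set, 6, small_geometry, enc, stimuli_per_subject=12, seed=6
    )


@pytest.fixture(scope="session")
def small_signal_dataset(stimulus_set, small_geometry):
    """8 subjects x 12 stimuli with a strong planted encoding."""
    enc = synthetic.random_encoding_spec(
        small_geometry, snr=8.0, signal_fraction=0.2, seed=15
    )
    return synthetic.generate_subject_betas(
        stimulus_set, 8, small_geometry, enc, stimuli_per_subject=12, seed=16
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
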
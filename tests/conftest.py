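import numpy as np
import pytest

from spdcnn.descriptor import describe_dataset
from spdcnn.synthetic import (
    SubjectSpec,
    generate_study,
    generate_subject_dataset,
    make_class_specs,
)


@pytest.fixture(scope="session")
def small_classes():
    """Four well-separated 12-channel class covariances."""
    return make_class_specs(n_classes=4, n_channels=12, seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_classes):
    """One subject, 12 trials/class, mild noise — fast unit-test fodder."""
    subject = SubjectSpec("S01", mixing_strength=0.1, seed=3)
    return generate_subject_dataset(
        subject, small_classes, n_trials_per_class=12, n_samples=128, noise_sd=1.0, seed=5
    )


@pytest.fixture(scope="session")
def multi_subject_study():
    """Four subjects with a visible domain shift; session-cached."""
    return generate_study(
        n_subjects=4, n_trials_per_class=20, n_samples=128, mixing_strength=0.3, seed=11
    )


@pytest.fixture(scope="session")
def normalized_samples(multi_subject_study):
    samples, stats = describe_dataset(multi_subject_study)
    return samples, stats


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
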
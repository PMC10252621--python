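import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kscem

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def mri_tree():
    return kscem.load_builtin_tree("mri")


@pytest.fixture(scope="session")
def cem_tree():
    return kscem.load_builtin_tree("cem")


@pytest.fixture(scope="session")
def fixture_spec():
    return kscem.default_fixture()


@pytest.fixture(scope="session")
def fixture_cohort(fixture_spec):
    return kscem.exact_count_cohort(fixture_spec, seed=7)


def spec_scores_labels(spec, modality):
    """Score vector and truth labels of one modality of a FixtureSpec."""
    scores = spec.scores("malignant", modality) + spec.scores("benign", modality)
    labels = ["malignant"] * spec.n_malignant + ["benign"] * spec.n_benign
    return scores, labels


@pytest.fixture(scope="session")
def mri_scores_labels(fixture_spec):
    return spec_scores_labels(fixture_spec, "mri")


@pytest.fixture(scope="session")
def cem_scores_labels(fixture_spec):
    return spec_scores_labels(fixture_spec, "cem")


def all_feature_vectors():
    """All 2*3*2*2*2 = 48 complete descriptor assignments."""
    names = list(kscem.flowchart.FEATURE_VALUES)
    for combo in itertools.product(*kscem.flowchart.FEATURE_VALUES.values()):
        yield kscem.LesionFeatures(**dict(zip(names, combo)))


def random_cohort(rng, m=None, n=None, lo=1, hi=12):
    """A random integer-scored two-class instance for property tests."""
    m = m or int(rng.integers(2, 12))
    n = n or int(rng.integers(2, 12))
    scores = np.concatenate([
        rng.integers(lo, hi + 1, m),
        rng.integers(lo, hi + 1, n),
    ])
    labels = np.array(["malignant"] * m + ["benign"] * n)
    return scores, labels
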
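import numpy as np
import pytest

from robustmeta import StudySet


@pytest.fixture
def small_set() -> StudySet:
    """Four studies with unequal precision; mild asymmetry."""
    return StudySet(
        estimates=[0.1, 0.3, 0.8, 0.2],
        std_errors=[0.1, 0.15, 0.4, 0.12],
    )


@pytest.fixture
def equal_weight_set() -> StudySet:
    return StudySet(estimates=[1.0, 2.0, 3.0, 10.0], std_errors=[0.5] * 4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


def random_study_set(rng: np.random.Generator, k: int | None = None) -> StudySet:
    """A random study set for property/oracle tests."""
    if k is None:
        k = int(rng.integers(2, 25))
    return StudySet(
        estimates=rng.normal(0.0, 2.0, size=k),
        std_errors=rng.uniform(0.05, 1.5, size=k),
    )
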
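import numpy as np
import pytest

from indexroc import Cohort, CohortSpec, ThresholdGrid, generate_cohort


@pytest.fixture
def hand_cohort() -> Cohort:
    """Four records: diseased {10, 3}, non-diseased {1, 8} µg/L."""
    return Cohort.from_records([(10, True), (3, True), (1, False), (8, False)])


@pytest.fixture
def separated_cohort() -> Cohort:
    """Perfect separation: diseased all at 100 µg/L, healthy all at 1."""
    return Cohort(
        values=np.array([100.0] * 5 + [1.0] * 20),
        diseased=np.array([True] * 5 + [False] * 20),
    )


@pytest.fixture(scope="session")
def default_grid() -> ThresholdGrid:
    return ThresholdGrid.default()


@pytest.fixture(scope="session")
def synthetic_cohort() -> Cohort:
    """Study-sized synthetic cohort (91 vs 1152, prevalence 0.073)."""
    return generate_cohort(CohortSpec(seed=20240430))


def random_cohort(rng: np.random.Generator, n: int = 50) -> Cohort:
    """Small random cohort with ties, for oracle comparisons."""
    values = np.round(rng.lognormal(2.0, 1.0, n), 1)
    diseased = rng.random(n) < 0.4
    if diseased.all() or not diseased.any():
        diseased[0] = not diseased[0]
    return Cohort(values=np.maximum(values, 0.5), diseased=diseased)
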
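import numpy as np
import pytest

from fairsurv import SurvivalCohort


@pytest.fixture
def tiny_cohort() -> SurvivalCohort:
    """5 subjects, 2 groups, distinct times, mixed censoring."""
    return SurvivalCohort(
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        event=np.array([1, 1, 0, 1, 0]),
        group=np.array([1, 2, 1, 2, 1]),
        covariates=np.array([[0.1], [0.2], [0.3], [0.4], [0.5]]),
        feature_names=("x1",),
        group_names=("a", "b"),
    )


def random_cohort(rng: np.random.Generator, n: int, k: int = 3) -> SurvivalCohort:
    """Random small cohort with ties in times and scores possible."""
    return SurvivalCohort(
        time=rng.integers(1, max(3, n // 2), size=n).astype(float),
        event=rng.integers(0, 2, size=n),
        group=rng.integers(1, k + 1, size=n),
        covariates=rng.standard_normal((n, 2)),
        feature_names=("x1", "x2"),
        group_names=tuple(f"g{i}" for i in range(1, k + 1)),
    )
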
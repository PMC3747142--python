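import numpy as np
import pytest

from netclust import BehaviorTable, Cohort, SyntheticSpec, generate_cohort
from netclust.labels import default_labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_symmetric_stack(rng, n_subjects, n_nodes, integer=True, scale=20.0):
    """Random valid cohort matrices: symmetric, zero-diagonal, non-negative."""
    mats = []
    for _ in range(n_subjects):
        a = rng.random((n_nodes, n_nodes)) * scale
        a = (a + a.T) / 2
        if integer:
            a = np.round(a)
        np.fill_diagonal(a, 0)
        mats.append(a)
    return np.stack(mats)


@pytest.fixture
def toy_cohort(rng):
    """10 subjects, 4 nodes (6 edges)."""
    mats = make_symmetric_stack(rng, 10, 4)
    subjects = [f"S{i:02d}" for i in range(10)]
    return Cohort(subjects=subjects, matrices=mats,
                  node_labels=default_labels(4))


@pytest.fixture
def toy_behavior(rng, toy_cohort):
    import pandas as pd

    n = toy_cohort.n_subjects
    return BehaviorTable(
        subjects=list(toy_cohort.subjects),
        measure=rng.random(n) * 10,
        measure_name="severity",
        covariates=pd.DataFrame({"age": 70 + 5 * rng.random(n)}),
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong planted effect: 20-edge connected cluster at rho = -0.5."""
    spec = SyntheticSpec(n_subjects=40, n_nodes=30, planted_k=20,
                         rho_target=-0.5, seed=77)
    return generate_cohort(spec)
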
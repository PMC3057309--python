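import numpy as np
import pandas as pd
import pytest

from imputebench.cohort import CohortConfig, CompleteCohort, generate_cohort
from imputebench.missingness import MissingnessSpec, default_spec, induce_mar


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def masked(cohort):
    """Default study condition: 50% stochastic MAR on f1 predicted by b1."""
    return induce_mar(cohort, default_spec(cohort, fraction=0.5, seed=11))


@pytest.fixture(scope="session")
def masked_rank(cohort):
    """Exact-fraction variant: exactly ceil(0.5 * 124) = 62 cells deleted."""
    spec = MissingnessSpec(
        target_variable=cohort.selected_followup,
        predictor_variable=cohort.selected_baseline,
        fraction=0.5,
        mechanism="MAR_rank",
        seed=11,
    )
    return induce_mar(cohort, spec)


def make_cohort_from_frame(frame: pd.DataFrame, n_days: int) -> CompleteCohort:
    """Tiny hand-built cohorts for algebraic oracle tests."""
    return CompleteCohort(data=frame, selected_followup="f1", n_days_per_wave=n_days)


@pytest.fixture
def tiny_cohort():
    """4 participants, 2 days per wave, hand-set counts."""
    frame = pd.DataFrame(
        {
            "b1": [5, 2, 0, 7],
            "b2": [4, 1, 0, 6],
            "f1": [3, 2, 0, 6],
            "f2": [2, 2, 1, 5],
        },
        index=pd.Index([f"P{i}" for i in range(1, 5)], name="pid"),
    )
    return make_cohort_from_frame(frame, n_days=2)


@pytest.fixture(scope="session")
def generated_batch():
    """200 default-config cohorts; shared by the calibration checks."""
    cohorts = [generate_cohort(CohortConfig(seed=s)) for s in range(200)]
    return cohorts


def assert_observed_preserved(masked, completed):
    """Observed cells must be bit-exact in every completed dataset."""
    truth = masked.cohort.data
    mask = masked.mask
    for d in completed.datasets:
        if d.shape == truth.shape:
            lhs = d.to_numpy(float)[mask.to_numpy()]
            rhs = truth.to_numpy(float)[mask.to_numpy()]
        else:  # complete cases: reduced rows
            keep = mask.all(axis=1)
            lhs = d.to_numpy(float).ravel()
            rhs = truth.loc[keep].to_numpy(float).ravel()
        np.testing.assert_array_equal(lhs, rhs)
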
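"""Complete cases, mean imputation, LOCF/LOCB: algebraic oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import assert_observed_preserved, make_cohort_from_frame
from imputebench.basic import complete_cases, locb, locf, mean_impute
from imputebench.cohort import CohortConfig, generate_cohort
from imputebench.errors import CarryError, DegenerateDataError
from imputebench.missingness import induce_mcar


def test_no_missing_is_identity(cohort):
    m = induce_mcar(cohort, "f1", 0.0, seed=0)
    for fn in (complete_cases, mean_impute, locf):
        out = fn(m)
        assert out.m == 1
        pd.testing.assert_frame_equal(out.first, cohort.data.astype(float))


def test_complete_cases_row_count(masked_rank):
    out = complete_cases(masked_rank)
    assert len(out.first) == 62  # 124 - 62 deleted
    assert out.provenance["n_retained"] == 62
    assert not out.first.isna().any().any()


def test_complete_cases_none_left(tiny_cohort):
    m = induce_mcar(tiny_cohort, "f1", 1.0, seed=0, exact=True)
    with pytest.raises(DegenerateDataError):
        complete_cases(m)


def test_complete_cases_unbiased_under_mcar():
    """Simulation oracle: under MCAR the retained-case mean is an unbiased
    estimator of the true mean."""
    biases = []
    for s in range(500):
        cohort = generate_cohort(CohortConfig(seed=50_000 + s))
        m = induce_mcar(cohort, "f1", 0.5, seed=60_000 + s)
        if m.n_complete_cases == 0:
            continue
        cc = complete_cases(m)
        biases.append(cc.first["f1"].mean() - cohort.data["f1"].mean())
    biases = np.asarray(biases)
    se = biases.std(ddof=1) / np.sqrt(len(biases))
    assert abs(biases.mean()) < 4 * se + 1e-12


def test_complete_cases_biased_down_under_mar(masked):
    """With a positively correlated predictor driving deletion, dropping
    incomplete rows underestimates the mean."""
    cc = complete_cases(masked)
    assert cc.first["f1"].mean() < masked.cohort.data["f1"].mean()


def test_mean_impute_hand_example():
    frame = pd.DataFrame(
        {
            "b1": [1, 1, 1, 1],
            "f1": [2.0, 4.0, np.nan, np.nan],
        },
        index=pd.Index(list("abcd"), name="pid"),
    )
    cohort = make_cohort_from_frame(frame.fillna(0).astype(int), n_days=1)
    m = induce_mcar(cohort, "f1", 0.0, seed=0)
    m.mask.loc[["c", "d"], "f1"] = False
    out = mean_impute(m)
    assert (out.first.loc[["c", "d"], "f1"] == 3.0).all()
    assert out.first["f1"].mean() == 3.0


def test_mean_impute_preserves_observed_mean(masked):
    out = mean_impute(masked)
    obs = masked.observed_frame()["f1"].dropna()
    assert out.first["f1"].mean() == pytest.approx(obs.mean(), rel=1e-12)


def test_mean_impute_variance_shrinkage_exact(masked):
    """Completed-column sample variance is exactly s^2 (n_obs-1)/(n-1):
    the 'artificially small confidence intervals' pathology."""
    out = mean_impute(masked)
    obs = masked.observed_frame()["f1"].dropna()
    n, n_obs = len(out.first), len(obs)
    expected = obs.var(ddof=1) * (n_obs - 1) / (n - 1)
    assert out.first["f1"].var(ddof=1) == pytest.approx(expected, rel=1e-12)


def test_mean_impute_fully_missing_column(tiny_cohort):
    m = induce_mcar(tiny_cohort, "f1", 1.0, seed=0, exact=True)
    with pytest.raises(DegenerateDataError):
        mean_impute(m)


def test_locf_carries_baseline_forward(tiny_cohort):
    m = induce_mcar(tiny_cohort, "f1", 0.0, seed=0)
    m.mask.loc["P1", "f1"] = False  # baseline b1 = 5
    out = locf(m)
    assert out.first.loc["P1", "f1"] == 5.0
    assert out.method_label == "locf"


def test_locb_carries_followup_backward(tiny_cohort):
    m = induce_mcar(tiny_cohort, "b1", 0.0, seed=0)
    m.mask.loc["P2", "b1"] = False  # follow-up f1 = 2
    out = locb(m)
    assert out.first.loc["P2", "b1"] == 2.0


def test_locf_bias_oracle():
    """If true follow-up = baseline - 2 everywhere and exactly half the
    follow-ups go missing, LOCF inflates the column mean by exactly
    2 * 0.5 = 1.0."""
    rng = np.random.default_rng(5)
    n = 124
    b = rng.integers(2, 12, size=n)
    frame = pd.DataFrame(
        {"b1": b, "f1": b - 2},
        index=pd.Index([f"P{i}" for i in range(n)], name="pid"),
    )
    cohort = make_cohort_from_frame(frame, n_days=1)
    m = induce_mcar(cohort, "f1", 0.5, seed=7, exact=True)
    out = locf(m)
    assert out.first["f1"].mean() - frame["f1"].mean() == pytest.approx(1.0)


def test_locf_missing_source_raises(tiny_cohort):
    m = induce_mcar(tiny_cohort, "f1", 0.0, seed=0)
    m.mask.loc["P1", "f1"] = False
    m.mask.loc["P1", "b1"] = False
    with pytest.raises(CarryError):
        locf(m)


def test_observed_cell_preservation_bit_exact(masked):
    for fn in (complete_cases, mean_impute, locf):
        assert_observed_preserved(masked, fn(masked))
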
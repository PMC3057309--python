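"""Validity t tests, coverage, bootstrap harness, full-study orchestration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from imputebench.errors import ValidationError
from imputebench.evaluation import (
    bootstrap_study,
    coverage,
    reference_interval,
    run_full_study,
    two_sample_t,
)
from imputebench.missingness import MissingnessSpec
from imputebench.multiple import MISettings


# -------------------------------------------------------------------- t test


def test_identical_groups_zero():
    r = two_sample_t(2.62, 5.22, 124, 2.62, 5.22, 124)
    assert r.t == 0.0
    assert r.cohens_d == 0.0
    assert r.p == pytest.approx(1.0)
    assert r.df == 246


def test_t_sign_follows_mean_difference():
    r = two_sample_t(1.39, 1.73, 124, 2.62, 5.22, 124)
    assert r.t < 0
    assert np.sign(r.t) == np.sign(r.mean_1 - r.mean_2)
    assert 0 <= r.p <= 1


@settings(derandomize=True, max_examples=300)
@given(
    m1=st.floats(-10, 10),
    m2=st.floats(-10, 10),
    s1=st.floats(0.1, 10),
    s2=st.floats(0.1, 10),
    n1=st.integers(2, 500),
    n2=st.integers(2, 500),
)
def test_t_matches_scipy_reference(m1, m2, s1, s2, n1, n2):
    """Oracle equivalence with scipy's pooled t from summary statistics."""
    ours = two_sample_t(m1, s1, n1, m2, s2, n2)
    ref_t, ref_p = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=True
    )
    assert ours.t == pytest.approx(float(ref_t), rel=1e-9, abs=1e-9)
    assert ours.p == pytest.approx(float(ref_p), rel=1e-6, abs=1e-9)
    assert ours.df == n1 + n2 - 2


def test_t_validation():
    with pytest.raises(ValidationError):
        two_sample_t(1, 1, 1, 2, 1, 124)
    with pytest.raises(ValidationError):
        two_sample_t(1, 0, 124, 2, 0, 124)
    with pytest.raises(ValidationError):
        two_sample_t(1, -1, 124, 2, 1, 124)


# ------------------------------------------------------------------ coverage


def test_coverage_bounds_and_counts():
    means = [0.0] * 70 + [99.0] * 5
    r = coverage(means, (-1.0, 1.0))
    assert r.n_inside == 70
    assert r.n_total == 75
    assert r.coverage_proportion == pytest.approx(70 / 75)
    assert coverage([0.0] * 10, (-1, 1)).coverage_proportion == 1.0
    assert coverage([5.0] * 10, (-1, 1)).coverage_proportion == 0.0


def test_coverage_inclusive_endpoints_and_failures():
    r = coverage([1.0, -1.0, np.nan], (-1.0, 1.0))
    assert r.n_inside == 2
    assert r.n_total == 2
    assert r.n_failed == 1


def test_coverage_validation():
    with pytest.raises(ValidationError):
        coverage([], (0, 1))
    with pytest.raises(ValidationError):
        coverage([1.0], (1, 0))


def test_reference_interval_width_shrinks_with_n():
    rng = np.random.default_rng(0)
    v = rng.standard_normal(320) * 5.22 + 2.62
    widths = []
    for n in (20, 80, 320):
        _m, sd, (lo, hi) = reference_interval(v[:n])
        widths.append((hi - lo) / sd)  # normalize out sample-sd noise
    assert widths[0] > widths[1] > widths[2]


# ----------------------------------------------------------------- bootstrap


def test_bootstrap_deterministic(masked):
    a = bootstrap_study(masked, approaches=["mean_imputation", "locf"], B=10, seed=5)
    b = bootstrap_study(masked, approaches=["mean_imputation", "locf"], B=10, seed=5)
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_complete_cases_equals_mean_imputation_pairwise(masked):
    """Mean imputation preserves the observed mean, so the two approaches'
    bootstrap means coincide resample by resample (Table-3-style identical
    variances)."""
    out = bootstrap_study(
        masked, approaches=["complete_cases", "mean_imputation"], B=75, seed=9
    )
    np.testing.assert_allclose(
        out["complete_cases"], out["mean_imputation"], rtol=1e-12
    )


def test_bootstrap_identity_approaches_agree_when_complete(cohort):
    """With nothing missing every approach returns the resample itself, so
    all approaches produce identical mean sequences."""
    from imputebench.missingness import induce_mcar

    m = induce_mcar(cohort, "f1", 0.0, seed=0)
    out = bootstrap_study(
        m,
        approaches=["complete_cases", "mean_imputation", "locf", "em_imputation"],
        B=5,
        seed=3,
    )
    base = out["complete_cases"]
    for k, v in out.items():
        np.testing.assert_allclose(v, base, rtol=1e-9)


# ---------------------------------------------------------------- full study


@pytest.fixture(scope="module")
def small_study():
    return run_full_study(B=10, mi_settings=MISettings(m=3), master_seed=77)


def test_study_structure(small_study):
    t2 = small_study.table2_frame()
    assert list(t2["method"]) == ["reference"] + [r.label for r in small_study.rows]
    assert len(small_study.rows) == 9
    t3 = small_study.table3_frame()
    assert len(t3) == 9
    assert small_study.reference_n == 124
    lo, hi = small_study.reference_ci
    assert lo < small_study.reference_mean < hi
    # complete cases analyzed at its own reduced n
    cc = small_study.row("complete_cases")
    assert cc.n < 124
    assert cc.test.df == cc.n + 124 - 2


def test_study_determinism(small_study):
    again = run_full_study(B=10, mi_settings=MISettings(m=3), master_seed=77)
    assert again.table2_frame().equals(small_study.table2_frame())
    assert again.table3_frame().equals(small_study.table3_frame())


def test_study_figure_exports(small_study):
    fig1 = small_study.figure1_observations
    assert "reference" in fig1.columns
    assert fig1.shape[0] == 124
    fig2 = small_study.figure2_frame()
    assert set(fig2["method"]) == set(r.label for r in small_study.rows)
    assert (fig2.groupby("method").size() == 10).all()


def test_study_report_json_roundtrip(small_study, tmp_path):
    path = tmp_path / "report.json"
    small_study.to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert payload["reference"]["n"] == 124
    assert len(payload["rows"]) == 9


def test_study_no_missingness_all_valid():
    """fraction = 0: every approach reproduces the reference exactly, so all
    t statistics are 0; bootstrapped means still scatter with resampling, so
    coverage sits near the nominal 95%."""
    spec = MissingnessSpec(
        target_variable="f1", predictor_variable="b1", fraction=0.0
    )
    rep = run_full_study(
        missingness_spec=spec, B=40, mi_settings=MISettings(m=3), master_seed=5
    )
    for r in rep.rows:
        assert r.test.t == 0.0
        assert r.coverage.coverage_proportion >= 0.85
    assert rep.realized_missing_fraction == 0.0
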
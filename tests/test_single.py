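"""Stochastic regression imputation and EM imputation."""

import numpy as np
import pandas as pd
import pytest

from conftest import assert_observed_preserved, make_cohort_from_frame
from imputebench import mvnorm
from imputebench.cohort import CohortConfig, generate_cohort
from imputebench.errors import DegenerateDataError
from imputebench.missingness import default_spec, induce_mar, induce_mcar
from imputebench.registry import ols_impute_array
from imputebench.single import em_fit, em_impute, regression_impute


# ---------------------------------------------------------------- regression


def test_regression_noiseless_recovers_exact_linear(cohort):
    """If the target is exactly linear in a predictor, noiseless regression
    imputation recovers the true values exactly under any MAR pattern."""
    n = 124
    rng = np.random.default_rng(3)
    b = rng.integers(0, 15, size=n)
    frame = pd.DataFrame(
        {"b1": b, "f1": 3 * b + 1},
        index=pd.Index([f"P{i}" for i in range(n)], name="pid"),
    )
    c = make_cohort_from_frame(frame, n_days=1)
    m = induce_mar(c, default_spec(c, fraction=0.5, seed=4))
    out = regression_impute(m, noise=False)
    np.testing.assert_allclose(out.first["f1"], frame["f1"], rtol=0, atol=1e-8)


def test_regression_identity_when_complete(cohort):
    m = induce_mcar(cohort, "f1", 0.0, seed=0)
    out = regression_impute(m, seed=0)
    pd.testing.assert_frame_equal(out.first, cohort.data.astype(float))


def test_regression_noise_variance_decomposition(masked):
    """Variance-decomposition oracle: across noise redraws on a fixed masked
    cohort, the completed-column variance averages the noiseless variance
    plus residual variance times the missing fraction."""
    base = regression_impute(masked, noise=False)
    var0 = base.first["f1"].var(ddof=0)
    resvar = base.provenance["fits"]["f1"]["residual_variance"]
    frac = masked.observed_frame()["f1"].isna().mean()
    varis = [
        regression_impute(masked, noise=True, seed=s).first["f1"].var(ddof=0)
        for s in range(500)
    ]
    expected = var0 + resvar * frac
    assert np.mean(varis) == pytest.approx(expected, rel=0.05)


def test_regression_kernel_matches_public_api(masked):
    """The array kernel used by the study harness and the statsmodels-backed
    public function are the same algorithm (noiseless route)."""
    out = regression_impute(masked, noise=False)
    frame = masked.observed_frame()
    arr = ols_impute_array(
        frame.to_numpy(float),
        frame.isna().to_numpy(),
        [frame.columns.get_loc(c) for c in masked.cohort.baseline_columns],
        False,
        np.random.default_rng(0),
    )
    np.testing.assert_allclose(arr, out.first.to_numpy(float), atol=1e-8)


def test_regression_too_few_complete_cases(tiny_cohort):
    m = induce_mcar(tiny_cohort, "f1", 0.75, seed=1, exact=True)
    with pytest.raises(DegenerateDataError):
        regression_impute(m)


# ------------------------------------------------------------------------ EM


def test_em_full_data_gives_sample_moments(cohort):
    m = induce_mcar(cohort, "f1", 0.0, seed=0)
    params = em_fit(m)
    X = cohort.data.to_numpy(float)
    np.testing.assert_allclose(params.mean.to_numpy(), X.mean(axis=0), rtol=1e-10)
    dev = X - X.mean(axis=0)
    np.testing.assert_allclose(
        params.covariance.to_numpy(), dev.T @ dev / len(X), rtol=1e-8
    )
    assert params.converged


def test_em_loglik_monotone_on_random_problems():
    """EM ascent: the observed-data log-likelihood never decreases, over 100
    random multi-pattern problems."""
    rng = np.random.default_rng(12)
    for _ in range(100):
        n, p = 40, 3
        A = rng.normal(size=(p, p))
        X = rng.normal(size=(n, p)) @ A + rng.normal(size=p)
        miss = rng.random((n, p)) < 0.25
        miss[:, 0] = False  # keep one anchor column complete
        res = mvnorm.em_mvnorm(X, miss, tol=1e-8, max_iter=200, track_loglik=True)
        ll = np.asarray(res.loglik_path)
        assert (np.diff(ll) >= -1e-8).all()


def test_em_closed_form_matches_iterative(masked):
    """The monotone single-column shortcut is the same fixed point as the
    iterative EM run to tight tolerance."""
    frame = masked.observed_frame()
    X, miss = frame.to_numpy(float), frame.isna().to_numpy()
    fast = mvnorm.em_mvnorm(X, miss, track_loglik=False)
    slow = mvnorm.em_mvnorm(X, miss, tol=1e-10, max_iter=5000, track_loglik=True)
    np.testing.assert_allclose(fast.mu, slow.mu, atol=1e-6)
    np.testing.assert_allclose(fast.sigma, slow.sigma, rtol=1e-5, atol=1e-5)


def _bivariate_mar(n, seed, rho=0.6, frac=0.3):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    X = np.column_stack([z[:, 0], 2.62 + z[:, 1]])
    from scipy.optimize import brentq
    from scipy.special import expit

    a = brentq(lambda b: expit(b + 1.5 * z[:, 0]).mean() - frac, -30, 30)
    miss = np.zeros((n, 2), bool)
    miss[:, 1] = rng.random(n) < expit(a + 1.5 * z[:, 0])
    return X, miss


def test_em_parameter_recovery_bivariate():
    """n = 2000 bivariate normal, 30% MAR on variable 2: the EM mean of the
    incomplete variable lands within +/-0.1 of the truth."""
    X, miss = _bivariate_mar(2000, seed=21)
    res = mvnorm.em_mvnorm(X, miss, track_loglik=False)
    assert abs(res.mu[1] - 2.62) < 0.1


def test_em_consistency_with_n():
    """Parameter RMSE shrinks as n grows (MCAR/MAR bivariate normal)."""
    rmse = {}
    for n in (100, 1000, 10000):
        errs = []
        for s in range(20):
            X, miss = _bivariate_mar(n, seed=1000 * n + s)
            res = mvnorm.em_mvnorm(X, miss, track_loglik=False)
            errs.append((res.mu[1] - 2.62) ** 2)
        rmse[n] = np.sqrt(np.mean(errs))
    assert rmse[100] > rmse[1000] > rmse[10000]


def test_em_impute_identity_when_complete(cohort):
    m = induce_mcar(cohort, "f1", 0.0, seed=0)
    out = em_impute(m)
    pd.testing.assert_frame_equal(out.first, cohort.data.astype(float))


def test_em_impute_marginal_mean_when_no_information():
    """If the observed target values carry no covariance with the other
    columns (constant observed target), imputations are the EM marginal
    mean of the target column."""
    frame = pd.DataFrame(
        {
            "b1": [1, 2, 3, 4, 5, 6],
            "f1": [4, 4, 4, 4, 4, 4],
        },
        index=pd.Index([f"P{i}" for i in range(6)], name="pid"),
    )
    c = make_cohort_from_frame(frame, n_days=1)
    m = induce_mcar(c, "f1", 0.0, seed=0)
    m.mask.loc[["P4", "P5"], "f1"] = False
    out = em_impute(m)
    assert out.first.loc[["P4", "P5"], "f1"].to_numpy() == pytest.approx([4.0, 4.0])


def test_em_less_biased_than_mean_imputation():
    """Paired simulation oracle over replicated MAR studies: EM imputation's
    completed-column mean is far less biased than mean imputation's."""
    em_b, mn_b = [], []
    for s in range(300):
        cohort = generate_cohort(CohortConfig(seed=70_000 + s))
        masked = induce_mar(cohort, default_spec(cohort, fraction=0.5, seed=80_000 + s))
        frame = masked.observed_frame()
        X, miss = frame.to_numpy(float), frame.isna().to_numpy()
        fit = mvnorm.em_mvnorm(X, miss, track_loglik=False)
        Xc = mvnorm.conditional_impute(X, miss, fit.mu, fit.sigma)
        truth = cohort.data["f1"].mean()
        j = frame.columns.get_loc("f1")
        em_b.append(Xc[:, j].mean() - truth)
        mn_b.append(np.nanmean(frame["f1"]) - truth)
    assert abs(np.mean(em_b)) < abs(np.mean(mn_b))


def test_em_single_imputation_variance_deficiency():
    """Across replicates, conditional-mean imputation underestimates the
    reference variance of the completed column (the type-I-error warning
    motivating MI).  Tested on bivariate normal data, where the property is
    clean; on heavy-tailed counts the linear conditional means can
    overshoot in the convex tail and dilute it."""
    diffs = []
    for s in range(300):
        rng = np.random.default_rng(s)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=124)
        X = np.column_stack([z[:, 0], 2.62 + 5.22 * z[:, 1]])
        from scipy.optimize import brentq
        from scipy.special import expit

        a = brentq(lambda b: expit(b + 1.5 * z[:, 0]).mean() - 0.5, -30, 30)
        miss = np.zeros((124, 2), bool)
        miss[:, 1] = rng.random(124) < expit(a + 1.5 * z[:, 0])
        if miss[:, 1].sum() > 120:
            continue
        fit = mvnorm.em_mvnorm(X, miss, track_loglik=False)
        Xc = mvnorm.conditional_impute(X, miss, fit.mu, fit.sigma)
        diffs.append(Xc[:, 1].var(ddof=1) - X[:, 1].var(ddof=1))
    assert np.mean(diffs) < 0
    assert np.mean(np.asarray(diffs) < 0) > 0.9


def test_em_nonconvergence_flagged():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 3))
    miss = rng.random((30, 3)) < 0.3
    miss[:, 0] = False
    res = mvnorm.em_mvnorm(X, miss, tol=1e-14, max_iter=2, track_loglik=True)
    assert not res.converged
    assert res.n_iter == 2


def test_em_impute_preserves_observed(masked):
    assert_observed_preserved(masked, em_impute(masked))
    assert_observed_preserved(masked, regression_impute(masked, seed=1))
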
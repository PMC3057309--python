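"""Incomplete multivariate normal machinery (array level).

This module is the numerical core shared by EM imputation, normal-model
multiple imputation (data augmentation) and bootstrap-EM multiple
imputation.  Everything here works on plain numpy arrays:

* ``X``: an (n, p) float matrix whose missing entries are arbitrary
  (they are ignored wherever ``miss`` is True);
* ``miss``: an (n, p) boolean matrix, True = missing.

Rows are grouped by missingness pattern once and each pattern is handled
with a partitioned-covariance conditional normal: for observed block O and
missing block M,

    E[x_M | x_O] = mu_M + Sigma_MO Sigma_OO^{-1} (x_O - mu_O)
    Var[x_M | x_O] = Sigma_MM - Sigma_MO Sigma_OO^{-1} Sigma_OM

computed via Cholesky solves (numerically equivalent to the sweep-operator
formulation).  Near-singular covariances get a ridge of
``1e-8 * trace / p`` on the diagonal and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import DegenerateDataError, SamplerError

__all__ = [
    "EMResult",
    "pattern_groups",
    "em_mvnorm",
    "conditional_impute",
    "observed_loglik",
    "draw_posterior_params",
    "da_impute",
    "bootstrap_em_impute",
]

_LOG2PI = np.log(2.0 * np.pi)
_RIDGE_SCALE = 1e-8


@dataclass
class EMResult:
    mu: np.ndarray
    sigma: np.ndarray
    loglik_path: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    ridged: bool = False

    @property
    def loglik(self) -> float:
        return float(self.loglik_path[-1]) if self.loglik_path else float("nan")


def pattern_groups(miss: np.ndarray):
    """Group row indices by missingness pattern.

    Returns a list of ``(rows, mis_cols, obs_cols)`` index-array triples.
    """
    miss = np.asarray(miss, bool)
    n, p = miss.shape
    if not miss.any():
        return [(np.arange(n), np.array([], dtype=int), np.arange(p))]
    uniq, inv = np.unique(miss, axis=0, return_inverse=True)
    groups = []
    for k in range(len(uniq)):
        rows = np.flatnonzero(inv == k)
        mis = np.flatnonzero(uniq[k])
        obs = np.flatnonzero(~uniq[k])
        groups.append((rows, mis, obs))
    return groups


def _ridge(sigma: np.ndarray) -> np.ndarray:
    p = sigma.shape[0]
    eps = _RIDGE_SCALE * np.trace(sigma) / p
    if eps <= 0:
        eps = _RIDGE_SCALE
    return sigma + eps * np.eye(p)


def _chol_obs(sigma: np.ndarray, obs: np.ndarray):
    """Cholesky of the observed block, ridging on failure.

    Returns (factor, ridged_flag, possibly-updated sigma).
    """
    ridged = False
    for _ in range(40):
        try:
            c = linalg.cho_factor(
                sigma[np.ix_(obs, obs)], lower=True, check_finite=False
            )
            return c, ridged, sigma
        except linalg.LinAlgError:
            sigma = _ridge(sigma)
            ridged = True
    raise DegenerateDataError("covariance irreparably singular")


def _initial_params(X: np.ndarray, miss: np.ndarray):
    nobs = (~miss).sum(axis=0)
    if (nobs == 0).any():
        raise DegenerateDataError("a column has no observed values")
    Xm = np.where(miss, np.nan, X)
    mu = np.nanmean(Xm, axis=0)
    filled = np.where(miss, mu, X)
    dev = filled - filled.mean(axis=0)
    sigma = dev.T @ dev / X.shape[0]
    # guard zero-variance columns at start
    d = np.diag(sigma).copy()
    floor = max(d.max(), 1.0) * 1e-10
    bad = d < floor
    if bad.any():
        sigma[bad, bad] = floor
    return mu, sigma


def _single_column_mle(X: np.ndarray, miss: np.ndarray, j: int) -> EMResult:
    """Exact ML for a single incomplete column (monotone pattern).

    With only column ``j`` incomplete the likelihood factors into the
    marginal of the complete block (sample moments over all rows) times the
    conditional regression of ``x_j`` on that block (OLS over the rows where
    ``x_j`` is observed, ML residual variance).  Reassembling the joint
    parameters gives the EM fixed point in closed form.
    """
    n, p = X.shape
    others = np.delete(np.arange(p), j)
    obs = ~miss[:, j]
    n_obs = int(obs.sum())
    if n_obs < 2:
        raise DegenerateDataError("need >= 2 observed values in the incomplete column")
    Xo = X[:, others]
    mu_o = Xo.mean(axis=0)
    dev_o = Xo - mu_o
    S_oo = dev_o.T @ dev_o / n
    Z = np.column_stack([np.ones(n_obs), Xo[obs]])
    y = X[obs, j]
    beta, _res, _rank, _sv = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    tau2 = float(resid @ resid) / n_obs
    b = beta[1:]
    mu = np.empty(p)
    sigma = np.empty((p, p))
    mu[others] = mu_o
    mu[j] = beta[0] + b @ mu_o
    sigma[np.ix_(others, others)] = S_oo
    s_oj = S_oo @ b
    sigma[others, j] = s_oj
    sigma[j, others] = s_oj
    sigma[j, j] = tau2 + float(b @ s_oj)
    return EMResult(mu=mu, sigma=sigma, n_iter=1, converged=True)


def em_mvnorm(
    X: np.ndarray,
    miss: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 500,
    track_loglik: bool = True,
    groups=None,
) -> EMResult:
    """ML estimation of (mu, Sigma) from incomplete data by EM.

    The E-step fills per-pattern conditional means and adds the conditional
    covariance correction to the second-moment sufficient statistic; the
    M-step re-estimates mean and covariance (MLE, n denominator).
    Convergence: max parameter change, measured relative to each
    parameter's scale (``|change| / (1 + |value|)``), below ``tol``.  The
    recorded log-likelihood path is the observed-data log-likelihood
    evaluated at the parameters entering each E-step, which EM never
    decreases.
    """
    X = np.asarray(X, float)
    miss = np.asarray(miss, bool)
    n, p = X.shape
    if n < 2:
        raise DegenerateDataError("need at least two rows")
    incomplete = np.flatnonzero(miss.any(axis=0))
    if not track_loglik and incomplete.size == 1 and p > 1:
        # monotone shortcut: closed-form MLE, identical fixed point
        return _single_column_mle(X, miss, int(incomplete[0]))
    if groups is None:
        groups = pattern_groups(miss)
    mu, sigma = _initial_params(X, miss)
    result = EMResult(mu=mu, sigma=sigma)

    # per-pattern constants: observed blocks never change across iterations
    prep = []
    base_x = np.zeros(p)
    base_xx = np.zeros((p, p))
    for rows, mis, obs in groups:
        Xo = X[np.ix_(rows, obs)]
        base_x[obs] += Xo.sum(axis=0)
        base_xx[np.ix_(obs, obs)] += Xo.T @ Xo
        if mis.size or track_loglik:
            prep.append(
                (
                    len(rows),
                    mis,
                    obs,
                    Xo,
                    np.ix_(obs, mis),
                    np.ix_(mis, obs),
                    np.ix_(mis, mis),
                )
            )

    for it in range(max_iter):
        sum_x = base_x.copy()
        sum_xx = base_xx.copy()
        ll = 0.0
        for n_rows, mis, obs, Xo, ix_om, ix_mo, ix_mm, in prep:
            cfac, ridged, sigma = _chol_obs(sigma, obs)
            result.ridged |= ridged
            dev = Xo - mu[obs]
            if track_loglik:
                alpha = linalg.cho_solve(cfac, dev.T, check_finite=False)
                quad = float(np.einsum("ij,ij->", dev.T, alpha))
                logdet = 2.0 * float(np.log(np.diag(cfac[0])).sum())
                ll -= 0.5 * (n_rows * (len(obs) * _LOG2PI + logdet) + quad)
            if mis.size:
                B = linalg.cho_solve(cfac, sigma[ix_om], check_finite=False)
                Xm = mu[mis] + dev @ B
                C = sigma[ix_mm] - sigma[ix_mo] @ B
                sum_x[mis] += Xm.sum(axis=0)
                cross = Xo.T @ Xm
                sum_xx[ix_om] += cross
                sum_xx[ix_mo] += cross.T
                sum_xx[ix_mm] += Xm.T @ Xm + n_rows * C
        if track_loglik:
            result.loglik_path.append(ll)
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        delta = max(
            float((np.abs(mu_new - mu) / (1.0 + np.abs(mu))).max()),
            float((np.abs(sigma_new - sigma) / (1.0 + np.abs(sigma))).max()),
        )
        mu, sigma = mu_new, sigma_new
        result.n_iter = it + 1
        if delta < tol:
            result.converged = True
            break
    result.mu, result.sigma = mu, sigma
    return result


def observed_loglik(X, miss, mu, sigma, groups=None) -> float:
    """Observed-data log-likelihood under N(mu, Sigma)."""
    X = np.asarray(X, float)
    if groups is None:
        groups = pattern_groups(np.asarray(miss, bool))
    ll = 0.0
    for rows, _mis, obs in groups:
        cfac, _r, sigma = _chol_obs(sigma, obs)
        dev = X[np.ix_(rows, obs)] - mu[obs]
        alpha = linalg.cho_solve(cfac, dev.T, check_finite=False)
        quad = float(np.einsum("ij,ij->", dev.T, alpha))
        logdet = 2.0 * float(np.log(np.diag(cfac[0])).sum())
        ll -= 0.5 * (len(rows) * (len(obs) * _LOG2PI + logdet) + quad)
    return ll


def conditional_impute(
    X, miss, mu, sigma, rng: np.random.Generator | None = None, groups=None
):
    """Fill missing cells with conditional means, or conditional draws when
    ``rng`` is given."""
    X = np.asarray(X, float)
    miss = np.asarray(miss, bool)
    out = X.copy()
    if groups is None:
        groups = pattern_groups(miss)
    for rows, mis, obs in groups:
        if not mis.size:
            continue
        cfac, _r, sigma = _chol_obs(sigma, obs)
        dev = X[np.ix_(rows, obs)] - mu[obs]
        B = linalg.cho_solve(cfac, sigma[np.ix_(obs, mis)], check_finite=False)
        Xm = mu[mis] + dev @ B
        if rng is not None:
            C = sigma[np.ix_(mis, mis)] - sigma[np.ix_(mis, obs)] @ B
            C = 0.5 * (C + C.T)
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                L = np.linalg.cholesky(_ridge(C))
            Xm = Xm + rng.standard_normal((len(rows), len(mis))) @ L.T
        out[np.ix_(rows, mis)] = Xm
    return out


def _bartlett_lower(df: float, p: int, rng: np.random.Generator) -> np.ndarray:
    """Lower-triangular Bartlett factor A with A A' ~ Wishart(df, I)."""
    A = np.zeros((p, p))
    A[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    return A


def draw_posterior_params(Xc: np.ndarray, rng: np.random.Generator):
    """One draw of (mu, Sigma) from the Jeffreys-prior posterior given a
    completed data matrix.

    Sigma | X ~ Inverse-Wishart(n - 1, S) with S the centered scatter
    matrix; mu | Sigma, X ~ N(xbar, Sigma / n).  The inverse-Wishart draw
    uses the Bartlett decomposition: Sigma = C A^{-T} A^{-1} C^T with
    S = C C^T and A A^T ~ Wishart(n - 1, I).
    """
    n, p = Xc.shape
    if n - 1 < p:
        raise DegenerateDataError("posterior draw needs n - 1 >= p")
    xbar = Xc.mean(axis=0)
    dev = Xc - xbar
    S = dev.T @ dev
    try:
        C = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        C = np.linalg.cholesky(_ridge(S))
    A = _bartlett_lower(n - 1, p, rng)
    M = linalg.solve_triangular(A, C.T, lower=True, check_finite=False)
    sigma = M.T @ M
    L = np.linalg.cholesky(sigma)
    mu = xbar + (L @ rng.standard_normal(p)) / np.sqrt(n)
    return mu, sigma


def da_impute(
    X,
    miss,
    m: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    groups=None,
    start: EMResult | None = None,
):
    """Normal-model data augmentation: alternate I-steps (conditional draws
    of the missing cells) and P-steps (posterior parameter draws), emitting
    ``m`` completed datasets after ``burn_in`` iterations, one every
    ``thin`` steps."""
    X = np.asarray(X, float)
    miss = np.asarray(miss, bool)
    if groups is None:
        groups = pattern_groups(miss)
    if start is None:
        start = em_mvnorm(X, miss, tol=1e-4, max_iter=200, track_loglik=False, groups=groups)
    mu, sigma = start.mu, start.sigma
    datasets = []
    total = burn_in + (m - 1) * thin + 1
    for t in range(total):
        Xc = conditional_impute(X, miss, mu, sigma, rng=rng, groups=groups)
        if not np.isfinite(Xc).all():
            raise SamplerError(f"non-finite I-step draw at iteration {t}")
        mu, sigma = draw_posterior_params(Xc, rng)
        if not (np.isfinite(mu).all() and np.isfinite(sigma).all()):
            raise SamplerError(f"non-finite P-step draw at iteration {t}")
        if t >= burn_in and (t - burn_in) % thin == 0:
            datasets.append(Xc.copy())
    return datasets


def bootstrap_em_impute(
    X,
    miss,
    m: int,
    rng: np.random.Generator,
    tol: float = 1e-4,
    max_iter: int = 500,
    max_retries: int = 10,
    groups=None,
):
    """Bootstrap-EM multiple imputation.

    For each of ``m`` imputations, a nonparametric bootstrap resample of the
    rows is drawn and EM is run on it; the ORIGINAL matrix's missing cells
    are then imputed from the conditional normal given those parameters
    (conditional mean plus a draw from the conditional covariance)."""
    X = np.asarray(X, float)
    miss = np.asarray(miss, bool)
    n = X.shape[0]
    if groups is None:
        groups = pattern_groups(miss)
    datasets = []
    for _j in range(m):
        fit = None
        for _attempt in range(max_retries):
            rows = rng.integers(0, n, size=n)
            sub_miss = miss[rows]
            try:
                fit = em_mvnorm(
                    X[rows], sub_miss, tol=tol, max_iter=max_iter, track_loglik=False
                )
                break
            except DegenerateDataError:
                fit = None
        if fit is None:
            raise SamplerError("EM failed on every bootstrap resample")
        Xc = conditional_impute(X, miss, fit.mu, fit.sigma, rng=rng, groups=groups)
        if not np.isfinite(Xc).all():
            raise SamplerError("non-finite bootstrap-EM imputation")
        datasets.append(Xc)
    return datasets
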
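"""Multiple imputation: three algorithm families.

``mi_norm``
    Normal-model data augmentation (I-step: draw missing cells from their
    conditional normal; P-step: draw (mu, Sigma) from the Jeffreys-prior
    normal/inverse-Wishart posterior given the completed data).  A
    "minimal" configuration of the same sampler — model restricted to the
    target variable and its paired baseline, short burn-in — emulates the
    under-specified default setups of early point-and-click MI modules; it
    is an emulation of that *style* of configuration, not a
    reverse-engineering of any particular program.

``mi_chained``
    Fully conditional specification (chained equations).  Each chain
    initializes missing cells with random draws from the observed values,
    then cycles through the incomplete variables, imputing each from a
    Bayesian linear regression on all other variables, with predictive mean
    matching (PMM) when ``pmm_donors > 0`` so imputations are always
    observed donor values (hence nonnegative integers for count data).

``mi_bootstrap_em``
    Bootstrap-EM: parameter uncertainty comes from running EM on
    nonparametric bootstrap resamples of the rows; the original dataset's
    missing cells are imputed from the conditional normal given each
    resample's parameters.

Normal-model imputations may be negative; they are retained untruncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from . import mvnorm
from .basic import CompletedData
from .errors import ConfigurationError, DegenerateDataError, SamplerError
from .missingness import MaskedCohort

__all__ = ["MISettings", "mi_norm", "mi_chained", "mi_bootstrap_em"]


@dataclass(frozen=True)
class MISettings:
    """Settings shared by the MI families.

    ``m`` is the number of imputed datasets (3..10 by convention, default
    5).  ``burn_in``/``between_chains`` steer the data-augmentation chain;
    with missingness confined to one column the chain has essentially no
    autocorrelation, so short runs are adequate.  ``pmm_donors=0`` switches
    chained equations from predictive mean matching to normal draws.
    """

    m: int = 5
    burn_in: int = 50
    between_chains: int = 25
    cycles: int = 10
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if self.burn_in < 1 or self.between_chains < 1 or self.cycles < 1:
            raise ConfigurationError("chain lengths must be positive")
        if self.pmm_donors < 0:
            raise ConfigurationError("pmm_donors must be >= 0")


def _wrap(
    frame: pd.DataFrame, arrays: list[np.ndarray], label: str, provenance: dict
) -> CompletedData:
    datasets = []
    notna = frame.notna()
    for arr in arrays:
        d = pd.DataFrame(arr, index=frame.index, columns=frame.columns)
        datasets.append(frame.where(notna, d))  # observed cells bit-exact
    return CompletedData(datasets=datasets, method_label=label, provenance=provenance)


def mi_norm(
    masked: MaskedCohort,
    settings: MISettings = MISettings(),
    model_columns: list[str] | None = None,
) -> CompletedData:
    """Data-augmentation MI under a joint normal model.

    ``model_columns`` restricts the normal model to a subset of columns
    (all incomplete columns must be inside it); the default uses every
    column.
    """
    frame = masked.observed_frame()
    cols = list(frame.columns) if model_columns is None else list(model_columns)
    incomplete = frame.columns[frame.isna().any()]
    if not set(incomplete) <= set(cols):
        raise ConfigurationError("model_columns must cover all incomplete columns")
    sub = frame[cols]
    X = sub.to_numpy(float)
    miss = sub.isna().to_numpy()
    rng = np.random.default_rng(settings.seed)
    if not miss.any():
        arrays = [frame.to_numpy(float)] * settings.m
        return _wrap(frame, arrays, "mi_norm", {"settings": settings.__dict__})
    subsets = mvnorm.da_impute(
        X, miss, settings.m, settings.burn_in, settings.between_chains, rng
    )
    arrays = []
    for s in subsets:
        full = frame.to_numpy(float).copy()
        full[:, [frame.columns.get_loc(c) for c in cols]] = s
        arrays.append(full)
    return _wrap(
        frame,
        arrays,
        "mi_norm",
        {"settings": settings.__dict__, "model_columns": cols},
    )


def _bayes_regression_draw(Z, y, rng):
    """Posterior draw (beta, sigma2) for y = Z beta + e, Jeffreys prior."""
    n, q = Z.shape
    if n <= q:
        raise DegenerateDataError("too few observed rows for the regression draw")
    G = Z.T @ Z
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        G = G + 1e-8 * np.trace(G) / q * np.eye(q)
        L = np.linalg.cholesky(G)
    beta_hat = linalg.cho_solve((L, True), Z.T @ y)
    resid = y - Z @ beta_hat
    rss = float(resid @ resid)
    sigma2 = rss / rng.chisquare(n - q)
    u = linalg.solve_triangular(L.T, rng.standard_normal(q), lower=False)
    beta = beta_hat + np.sqrt(sigma2) * u
    return beta_hat, beta, sigma2


def chained_arrays(
    X: np.ndarray,
    miss: np.ndarray,
    m: int,
    cycles: int,
    pmm_donors: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """m independent chained-equation chains on an array (see mi_chained)."""
    X = np.asarray(X, float)
    miss = np.asarray(miss, bool)
    n, p = X.shape
    incomplete = np.flatnonzero(miss.any(axis=0))
    for j in incomplete:
        if miss[:, j].all():
            raise DegenerateDataError("an incomplete column has no observed values")
    datasets = []
    for _chain in range(m):
        Xc = X.copy()
        for j in incomplete:
            obs_vals = X[~miss[:, j], j]
            Xc[miss[:, j], j] = rng.choice(obs_vals, size=int(miss[:, j].sum()))
        for _cycle in range(cycles):
            for j in incomplete:
                obs = ~miss[:, j]
                others = [k for k in range(p) if k != j]
                Z = np.column_stack([np.ones(n), Xc[:, others]])
                beta_hat, beta, sigma2 = _bayes_regression_draw(
                    Z[obs], Xc[obs, j], rng
                )
                if not np.isfinite(beta).all():
                    raise SamplerError("non-finite chained-equations draw")
                holes = miss[:, j]
                yhat_mis = Z[holes] @ beta
                if pmm_donors > 0:
                    yhat_obs = Z[obs] @ beta_hat
                    k = min(pmm_donors, int(obs.sum()))
                    dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
                    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
                    pick = nearest[
                        np.arange(len(yhat_mis)), rng.integers(0, k, len(yhat_mis))
                    ]
                    Xc[holes, j] = X[obs, j][pick]
                else:
                    Xc[holes, j] = yhat_mis + rng.normal(
                        0.0, np.sqrt(sigma2), size=int(holes.sum())
                    )
        datasets.append(Xc)
    return datasets


def mi_chained(
    masked: MaskedCohort, settings: MISettings = MISettings()
) -> CompletedData:
    """Chained-equations MI (m independent chains, PMM by default)."""
    frame = masked.observed_frame()
    X = frame.to_numpy(float)
    miss = frame.isna().to_numpy()
    rng = np.random.default_rng(settings.seed)
    if not miss.any():
        arrays = [X] * settings.m
    else:
        arrays = chained_arrays(
            X, miss, settings.m, settings.cycles, settings.pmm_donors, rng
        )
    return _wrap(frame, arrays, "mi_chained", {"settings": settings.__dict__})


def mi_bootstrap_em(
    masked: MaskedCohort,
    settings: MISettings = MISettings(),
    tol: float = 1e-4,
    max_iter: int = 500,
) -> CompletedData:
    """Bootstrap-EM MI (Amelia-style)."""
    frame = masked.observed_frame()
    X = frame.to_numpy(float)
    miss = frame.isna().to_numpy()
    rng = np.random.default_rng(settings.seed)
    if not miss.any():
        arrays = [X] * settings.m
    else:
        arrays = mvnorm.bootstrap_em_impute(
            X, miss, settings.m, rng, tol=tol, max_iter=max_iter
        )
    return _wrap(frame, arrays, "mi_bootstrap_em", {"settings": settings.__dict__})
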
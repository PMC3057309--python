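"""Rubin's rules for combining estimates across m imputed datasets.

Given per-dataset estimates Q_1..Q_m with variances U_1..U_m:

    Qbar = mean(Q_j)                      (pooled estimate)
    W    = mean(U_j)                      (within-imputation variance)
    B    = sample variance of the Q_j     (between-imputation variance)
    T    = W + (1 + 1/m) B                (total variance)
    df   = (m - 1) (1 + W / ((1 + 1/m) B))^2    (infinite when B = 0)

The degrees of freedom are the classic large-sample form; the small-sample
Barnard–Rubin adjustment is available behind a flag for analysts who know
their complete-data degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .basic import CompletedData
from .errors import ValidationError

__all__ = ["PooledEstimate", "rubin_pool", "pool_mean_analysis"]


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    m: int
    single_imputation: bool = False

    @property
    def se(self) -> float:
        return math.sqrt(self.total_variance)

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm, t

        if math.isinf(self.df):
            q = norm.ppf(0.5 + level / 2.0)
        else:
            q = t.ppf(0.5 + level / 2.0, self.df)
        half = q * self.se
        return (self.estimate - half, self.estimate + half)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "within_variance": self.within_variance,
            "between_variance": self.between_variance,
            "total_variance": self.total_variance,
            "df": self.df,
            "m": self.m,
            "single_imputation": self.single_imputation,
        }


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    barnard_rubin: bool = False,
    df_complete: float | None = None,
) -> PooledEstimate:
    """Combine m >= 2 per-dataset estimates and variances."""
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValidationError("estimates and variances must be equal-length 1-d")
    m = len(q)
    if m < 2:
        raise ValidationError("rubin_pool needs m >= 2 (single imputation has no B)")
    if (u < 0).any():
        raise ValidationError("variances must be nonnegative")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b > 0:
        rel = (1.0 + 1.0 / m) * b
        df = (m - 1) * (1.0 + w / rel) ** 2
        if barnard_rubin:
            if df_complete is None:
                raise ValidationError("barnard_rubin needs df_complete")
            lam = rel / t
            df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (
                1.0 - lam
            )
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
    else:
        df = math.inf
    return PooledEstimate(
        estimate=qbar,
        within_variance=w,
        between_variance=b,
        total_variance=t,
        df=float(df),
        m=m,
    )


def pool_mean_analysis(completed: CompletedData, variable: str) -> PooledEstimate:
    """Analyze each completed dataset (sample mean of ``variable``, variance
    s^2/n) and Rubin-combine the results.

    For m = 1 the result is a flagged passthrough: the between-imputation
    variance is undefined (reported as NaN) and the total variance equals
    the within variance.
    """
    ests, vars_ = [], []
    for d in completed.datasets:
        col = d[variable]
        n = len(col)
        ests.append(float(col.mean()))
        vars_.append(float(col.var(ddof=1)) / n)
    if completed.m == 1:
        return PooledEstimate(
            estimate=ests[0],
            within_variance=vars_[0],
            between_variance=float("nan"),
            total_variance=vars_[0],
            df=float(n - 1),
            m=1,
            single_imputation=True,
        )
    return rubin_pool(ests, vars_)
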
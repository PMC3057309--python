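"""Synthetic reference cohorts of daily drink counts.

The generator emulates a two-wave observational cohort of problem drinkers:
each participant reports seven daily alcohol consumption counts (standard
10 g ethanol units) at baseline and again at a 3-month follow-up.  The
counts are nonnegative integers, right-skewed, overdispersed (SD roughly
twice the mean) and zero-inflated, and follow-up drinking is positively
correlated with baseline drinking.

Generative model
----------------
* Per-participant latent severity: ``S = exp(mu + sigma * Z)`` with
  ``Z ~ N(0, 1)``; the follow-up ``Z`` is correlated with the baseline ``Z``
  at a latent level solved so that the *realized* correlation between
  baseline and follow-up weekly totals matches the configured value.
* Daily counts within a wave are negative binomial with mean ``S`` and
  dispersion ``r`` (independent days given severity).
* A wave-level abstinence indicator zeroes the whole week for a fraction of
  participants (the excess-zero mass: post-intervention abstainers at
  follow-up, a small fraction at baseline).
* Baseline severity carries a higher location: cohorts of this kind reduce
  their consumption between enrolment and follow-up, so the baseline mean
  defaults to twice the follow-up target mean.

All free parameters (``r`` and the latent correlation) are calibrated by
closed-form moment matching against the configured follow-up-day mean/SD and
weekly-total correlation, so generation is fully determined by the config
and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CohortConfig",
    "CompleteCohort",
    "SummaryStats",
    "generate_cohort",
    "summarize_variable",
]


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    n_participants:
        Number of rows (default 124, the reference cohort size).
    n_days_per_wave:
        Daily count columns per wave (default 7, one calendar week).
    target_mean, target_sd:
        Moments of the designated follow-up day variable, in drinks/day
        (defaults 2.62 and 5.22).
    zero_fraction:
        Probability that a participant is abstinent for the whole follow-up
        week (structural zeros; default 0.25).
    baseline_zero_fraction:
        Same for the baseline week (default 0.05; participants enrolled
        because they were drinking).
    baseline_mean:
        Marginal mean of a baseline day variable.  ``None`` (default) means
        ``2 * target_mean``, reflecting the roughly halved consumption
        between enrolment and follow-up in self-help cohorts.
    severity_log_sd:
        SD of the latent log-severity (default 1.1); controls skewness and
        the between-participant share of the variance.
    baseline_followup_correlation:
        Target Pearson correlation between baseline and follow-up weekly
        totals, in (0, 1); default 0.5.
    selected_day:
        1-based day index of the designated follow-up variable (default 1,
        i.e. column ``f1``; its paired baseline day is ``b1``).
    seed:
        Generation seed; identical config + seed gives identical cohorts.
    """

    n_participants: int = 124
    n_days_per_wave: int = 7
    target_mean: float = 2.62
    target_sd: float = 5.22
    zero_fraction: float = 0.25
    baseline_zero_fraction: float = 0.05
    baseline_mean: float | None = None
    severity_log_sd: float = 1.1
    baseline_followup_correlation: float = 0.5
    selected_day: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if self.n_days_per_wave < 1:
            raise ConfigurationError("n_days_per_wave must be >= 1")
        if self.target_sd <= 0:
            raise ConfigurationError("target_sd must be > 0")
        if self.target_mean <= 0:
            raise ConfigurationError("target_mean must be > 0")
        if not (0 <= self.zero_fraction < 1):
            raise ConfigurationError("zero_fraction must be in [0, 1)")
        if not (0 <= self.baseline_zero_fraction < 1):
            raise ConfigurationError("baseline_zero_fraction must be in [0, 1)")
        if not (0 < self.baseline_followup_correlation < 1):
            raise ConfigurationError(
                "baseline_followup_correlation must be in (0, 1)"
            )
        if self.severity_log_sd <= 0:
            raise ConfigurationError("severity_log_sd must be > 0")
        if not (1 <= self.selected_day <= self.n_days_per_wave):
            raise ConfigurationError("selected_day outside the follow-up wave")

    @property
    def effective_baseline_mean(self) -> float:
        return 2.0 * self.target_mean if self.baseline_mean is None else self.baseline_mean

    def derived_params(self) -> "GeneratorParams":
        return _calibrate(self)


@dataclass(frozen=True)
class GeneratorParams:
    """Moment-matched internal parameters (see module docstring)."""

    log_mu_followup: float
    log_mu_baseline: float
    log_sd: float
    dispersion: float
    latent_correlation: float


def _lognormal_moments(mean_count: float, zero_fraction: float, s: float):
    """First two moments of severity given the marginal day mean."""
    m1 = mean_count / (1.0 - zero_fraction)
    m2 = m1 * m1 * math.exp(s * s)
    return m1, m2


def _day_variance(m1: float, m2: float, pi: float, r: float) -> float:
    # Var(day) = within-person NB noise + severity/abstinence mixture spread
    return (1 - pi) * (m1 + m2 / r) + (1 - pi) * m2 - (1 - pi) ** 2 * m1 * m1


def _week_total_variance(m1, m2, pi, r, days):
    return days * days * ((1 - pi) * m2 - (1 - pi) ** 2 * m1 * m1) + days * (
        1 - pi
    ) * (m1 + m2 / r)


def _calibrate(config: CohortConfig) -> GeneratorParams:
    s = config.severity_log_sd
    pi_f = config.zero_fraction
    pi_b = config.baseline_zero_fraction
    m1f, m2f = _lognormal_moments(config.target_mean, pi_f, s)
    denom = (
        config.target_sd**2
        - (1 - pi_f) * m1f
        - (1 - pi_f) * m2f
        + (1 - pi_f) ** 2 * m1f * m1f
    )
    if denom <= 0:
        raise ConfigurationError(
            "target_sd too small for the configured zero_fraction/severity_log_sd: "
            "the severity mixture alone already exceeds the variance target"
        )
    r = (1 - pi_f) * m2f / denom
    m1b, m2b = _lognormal_moments(config.effective_baseline_mean, pi_b, s)

    days = config.n_days_per_wave
    var_tf = _week_total_variance(m1f, m2f, pi_f, r, days)
    var_tb = _week_total_variance(m1b, m2b, pi_b, r, days)
    scale = days * days * (1 - pi_f) * (1 - pi_b) * m1f * m1b

    def week_corr(rho_z: float) -> float:
        cov = scale * (math.exp(rho_z * s * s) - 1.0)
        return cov / math.sqrt(var_tf * var_tb)

    target = config.baseline_followup_correlation
    if week_corr(1.0) < target:
        raise ConfigurationError(
            f"baseline_followup_correlation={target} unattainable: the maximum "
            f"weekly-total correlation under this configuration is "
            f"{week_corr(1.0):.3f}"
        )
    rho_z = brentq(lambda r_: week_corr(r_) - target, 1e-12, 1.0, xtol=1e-12)
    return GeneratorParams(
        log_mu_followup=math.log(m1f) - s * s / 2.0,
        log_mu_baseline=math.log(m1b) - s * s / 2.0,
        log_sd=s,
        dispersion=r,
        latent_correlation=float(rho_z),
    )


@dataclass
class CompleteCohort:
    """Fully observed participant-by-variable table of counts.

    ``data`` has a ``pid`` index and columns ``b1..bD, f1..fD`` holding
    nonnegative integer drink counts; ``selected_followup`` names the
    designated follow-up day variable (e.g. ``"f1"``).
    """

    data: pd.DataFrame
    selected_followup: str
    n_days_per_wave: int = 7
    config: CohortConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValidationError("a CompleteCohort may not contain missing cells")
        if self.selected_followup not in self.data.columns:
            raise ValidationError(
                f"selected follow-up variable {self.selected_followup!r} not a column"
            )

    @property
    def n_participants(self) -> int:
        return len(self.data)

    @property
    def participant_ids(self) -> Sequence:
        return list(self.data.index)

    @property
    def baseline_columns(self) -> list[str]:
        return [f"b{i}" for i in range(1, self.n_days_per_wave + 1)]

    @property
    def followup_columns(self) -> list[str]:
        return [f"f{i}" for i in range(1, self.n_days_per_wave + 1)]

    @property
    def selected_baseline(self) -> str:
        """Baseline day paired with the selected follow-up day."""
        return "b" + self.selected_followup[1:]

    def carry_map(self) -> dict[str, str]:
        """Default LOCF pairing: follow-up day k <- baseline day k."""
        return dict(zip(self.followup_columns, self.baseline_columns))


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int


def generate_cohort(config: CohortConfig) -> CompleteCohort:
    """Draw a complete reference cohort from the calibrated count model."""
    params = config.derived_params()
    rng = np.random.default_rng(config.seed)
    n, days = config.n_participants, config.n_days_per_wave
    s = params.log_sd

    z_b = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    rho = params.latent_correlation
    z_f = rho * z_b + math.sqrt(1.0 - rho * rho) * eps

    sev_b = np.exp(params.log_mu_baseline + s * z_b)
    sev_f = np.exp(params.log_mu_followup + s * z_f)
    abstinent_b = rng.random(n) < config.baseline_zero_fraction
    abstinent_f = rng.random(n) < config.zero_fraction

    r = params.dispersion

    def wave_counts(severity: np.ndarray, abstinent: np.ndarray) -> np.ndarray:
        p = r / (r + severity)
        counts = rng.negative_binomial(r, p[:, None], size=(n, days))
        counts[abstinent] = 0
        return counts

    baseline = wave_counts(sev_b, abstinent_b)
    followup = wave_counts(sev_f, abstinent_f)

    pids = [f"P{i + 1:03d}" for i in range(n)]
    cols = [f"b{i}" for i in range(1, days + 1)] + [f"f{i}" for i in range(1, days + 1)]
    data = pd.DataFrame(
        np.hstack([baseline, followup]), index=pd.Index(pids, name="pid"), columns=cols
    )
    return CompleteCohort(
        data=data,
        selected_followup=f"f{config.selected_day}",
        n_days_per_wave=days,
        config=config,
    )


def summarize_variable(data, variable) -> SummaryStats:
    """Sample mean and SD (n-1 denominator) of one cohort variable.

    ``data`` may be a :class:`CompleteCohort` or a DataFrame; ``variable`` is
    a column label.
    """
    frame = data.data if isinstance(data, CompleteCohort) else data
    if variable not in frame.columns:
        raise KeyError(f"unknown column {variable!r}")
    col = frame[variable].dropna()
    if len(col) == 0:
        raise ValidationError("empty selection: no observed values to summarize")
    return SummaryStats(
        mean=float(col.mean()), sd=float(col.std(ddof=1)), n=int(len(col))
    )


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Convenience: the same configuration with a different seed."""
    return replace(config, seed=int(seed))
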
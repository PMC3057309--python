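"""MCAR / MAR missingness induction on one target variable.

The MAR mechanisms condition deletion on a fully observed predictor column:
if the predictor score is high, the chance that the target value goes
missing is high.  Two operationalizations are provided:

``MAR_stochastic`` (default)
    Each case's deletion probability is a logistic function of its
    standardized predictor value, ``p_i = expit(a + k * z_i)``, with the
    intercept ``a`` solved numerically so the *expected* deleted fraction
    equals the requested fraction.  Realized fractions vary by seed.

``MAR_rank``
    Exactly ``ceil(fraction * n)`` cases are deleted: those with the highest
    predictor values after a small random jitter breaks ties.

Conditional on the predictor, deletion is independent of the target's own
value in both variants, which is what makes the mechanism MAR rather than
MNAR.  The pre-deletion values are retained inside the returned
:class:`MaskedCohort` as the hidden truth for evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import CompleteCohort
from .errors import ConfigurationError, MechanismError

__all__ = [
    "MissingnessSpec",
    "MaskedCohort",
    "induce_mar",
    "induce_mcar",
    "MECHANISMS",
]

MECHANISMS = ("MCAR", "MCAR_exact", "MAR_stochastic", "MAR_rank")


@dataclass(frozen=True)
class MissingnessSpec:
    """How missingness is imposed on one target column."""

    target_variable: str
    predictor_variable: str | None = None
    fraction: float = 0.50
    mechanism: Literal["MCAR", "MCAR_exact", "MAR_stochastic", "MAR_rank"] = (
        "MAR_stochastic"
    )
    steepness: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ConfigurationError("fraction must be in [0, 1]")
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"unknown mechanism {self.mechanism!r}; choose from {MECHANISMS}"
            )
        if self.mechanism.startswith("MAR"):
            if self.predictor_variable is None:
                raise ConfigurationError("MAR mechanisms need a predictor_variable")
            if self.predictor_variable == self.target_variable:
                raise ConfigurationError(
                    "predictor and target must differ for MAR mechanisms"
                )
        if self.steepness <= 0:
            raise ConfigurationError("steepness must be > 0")


@dataclass
class MaskedCohort:
    """A complete cohort plus a missingness mask.

    ``mask`` is aligned with ``cohort.data``; ``True`` means observed.  The
    underlying values are retained (hidden truth), so evaluation against the
    pre-deletion data is always possible from a MaskedCohort alone.
    """

    cohort: CompleteCohort
    mask: pd.DataFrame
    spec: MissingnessSpec
    realized_fraction: float = field(default=0.0)

    def observed_frame(self) -> pd.DataFrame:
        """The data as an imputer sees it: NaN wherever the mask is False."""
        return self.cohort.data.astype(float).where(self.mask)

    @property
    def n_missing(self) -> int:
        return int((~self.mask).to_numpy().sum())

    @property
    def n_complete_cases(self) -> int:
        return int(self.mask.all(axis=1).sum())

    def hidden_truth(self) -> pd.DataFrame:
        return self.cohort.data


def _full_mask(cohort: CompleteCohort) -> pd.DataFrame:
    return pd.DataFrame(
        True, index=cohort.data.index, columns=cohort.data.columns, dtype=bool
    )


def _check_target(cohort: CompleteCohort, column: str) -> None:
    if column not in cohort.data.columns:
        raise MechanismError(f"column {column!r} not in cohort")


def induce_mar(cohort: CompleteCohort, spec: MissingnessSpec) -> MaskedCohort:
    """Impose MAR (or MCAR, if so configured) missingness per ``spec``."""
    _check_target(cohort, spec.target_variable)
    if spec.mechanism.startswith("MCAR"):
        return induce_mcar(
            cohort,
            spec.target_variable,
            spec.fraction,
            spec.seed,
            exact=spec.mechanism == "MCAR_exact",
        )
    _check_target(cohort, spec.predictor_variable)
    predictor = cohort.data[spec.predictor_variable].to_numpy(float)
    if np.isnan(predictor).any():
        raise MechanismError("predictor column contains missing cells")

    n = len(predictor)
    rng = np.random.default_rng(spec.seed)
    if spec.fraction == 0.0:
        deleted = np.zeros(n, dtype=bool)
    elif spec.mechanism == "MAR_rank":
        k = math.ceil(spec.fraction * n)
        jitter = rng.uniform(-1e-9, 1e-9, size=n) * (1.0 + np.abs(predictor))
        order = np.argsort(predictor + jitter)
        deleted = np.zeros(n, dtype=bool)
        deleted[order[n - k :]] = True
    else:  # MAR_stochastic
        sd = predictor.std()
        z = (predictor - predictor.mean()) / sd if sd > 0 else np.zeros(n)
        k_ = spec.steepness

        def expected_fraction(intercept: float) -> float:
            return float(expit(intercept + k_ * z).mean())

        lo, hi = -50.0, 50.0
        if spec.fraction >= 1.0:
            deleted = np.ones(n, dtype=bool)
        else:
            a = brentq(
                lambda b: expected_fraction(b) - spec.fraction, lo, hi, xtol=1e-10
            )
            deleted = rng.random(n) < expit(a + k_ * z)

    mask = _full_mask(cohort)
    mask.loc[deleted, spec.target_variable] = False
    return MaskedCohort(
        cohort=cohort,
        mask=mask,
        spec=spec,
        realized_fraction=float(deleted.mean()),
    )


def induce_mcar(
    cohort: CompleteCohort,
    target_variable: str,
    fraction: float,
    seed: int = 0,
    exact: bool = False,
) -> MaskedCohort:
    """Delete target cells completely at random.

    ``exact=True`` deletes a simple random sample of ``ceil(fraction * n)``
    cases; otherwise each case is deleted independently with probability
    ``fraction``.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ConfigurationError("fraction must be in [0, 1]")
    _check_target(cohort, target_variable)
    n = cohort.n_participants
    rng = np.random.default_rng(seed)
    if exact:
        k = math.ceil(fraction * n)
        deleted = np.zeros(n, dtype=bool)
        deleted[rng.choice(n, size=k, replace=False)] = True
    else:
        deleted = rng.random(n) < fraction
    mask = _full_mask(cohort)
    mask.loc[deleted, target_variable] = False
    spec = MissingnessSpec(
        target_variable=target_variable,
        predictor_variable=None,
        fraction=fraction,
        mechanism="MCAR_exact" if exact else "MCAR",
        seed=seed,
    )
    return MaskedCohort(
        cohort=cohort, mask=mask, spec=spec, realized_fraction=float(deleted.mean())
    )


def default_spec(cohort: CompleteCohort, fraction: float = 0.5, seed: int = 0) -> MissingnessSpec:
    """The study's default mechanism: 50% stochastic MAR on the selected
    follow-up day, predicted by the same weekday's baseline value."""
    return MissingnessSpec(
        target_variable=cohort.selected_followup,
        predictor_variable=cohort.selected_baseline,
        fraction=fraction,
        mechanism="MAR_stochastic",
        steepness=1.5,
        seed=seed,
    )
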
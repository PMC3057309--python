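"""Basic missing-data approaches: complete cases, listwise mean imputation,
and last observation carried forward/backward.

These are the conceptually simple, computation-free approaches.  They are
known to be problematic — complete case analysis and mean imputation are
unbiased only under MCAR, mean imputation shrinks the variance by exactly
``(n_obs - 1)/(n - 1)``, and LOCF projects baseline levels onto missing
follow-ups — and the evaluation harness exists to quantify exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import CarryError, DegenerateDataError
from .missingness import MaskedCohort

__all__ = ["CompletedData", "complete_cases", "mean_impute", "locf", "locb"]


@dataclass
class CompletedData:
    """One (single imputation) or m (multiple imputation) completed tables.

    Every dataset has zero missing cells, and cells that were observed in
    the input are identical across all m datasets and equal to the input
    values.  ``datasets[0]`` is "the first imputed dataset" in strip-chart
    conventions.
    """

    datasets: list[pd.DataFrame]
    method_label: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in self.datasets:
            if d.isna().any().any():
                raise ValueError("a completed dataset may not contain missing cells")

    @property
    def m(self) -> int:
        return len(self.datasets)

    @property
    def first(self) -> pd.DataFrame:
        return self.datasets[0]


def complete_cases(masked: MaskedCohort) -> CompletedData:
    """Drop every row with at least one missing cell (casewise deletion).

    The returned dataset has fewer rows than the input; downstream
    statistics must use its own n.
    """
    observed = masked.observed_frame()
    keep = masked.mask.all(axis=1)
    if not keep.any():
        raise DegenerateDataError("no complete cases")
    return CompletedData(
        datasets=[observed.loc[keep]],
        method_label="complete_cases",
        provenance={"n_retained": int(keep.sum()), "n_input": len(observed)},
    )


def mean_impute(masked: MaskedCohort) -> CompletedData:
    """Replace each missing cell with its column's observed-value mean."""
    observed = masked.observed_frame()
    n_obs = observed.notna().sum()
    if (n_obs == 0).any():
        raise DegenerateDataError("a column has no observed values to average")
    filled = observed.fillna(observed.mean())
    return CompletedData(
        datasets=[filled],
        method_label="mean_imputation",
        provenance={"column_means": observed.mean().to_dict()},
    )


def _carry(masked: MaskedCohort, carry_map: dict[str, str], label: str) -> CompletedData:
    observed = masked.observed_frame()
    filled = observed.copy()
    for col in observed.columns[observed.isna().any()]:
        if col not in carry_map:
            raise CarryError(f"no carry source configured for column {col!r}")
        src = carry_map[col]
        holes = observed[col].isna()
        donor = observed.loc[holes, src]
        if donor.isna().any():
            raise CarryError(
                f"carry source {src!r} itself missing for some rows of {col!r}"
            )
        filled.loc[holes, col] = donor
    return CompletedData(
        datasets=[filled], method_label=label, provenance={"carry_map": dict(carry_map)}
    )


def locf(masked: MaskedCohort, carry_map: dict[str, str] | None = None) -> CompletedData:
    """Last observation carried forward: missing follow-up day k takes the
    participant's baseline day k value (default pairing)."""
    if carry_map is None:
        carry_map = masked.cohort.carry_map()
    return _carry(masked, carry_map, "locf")


def locb(masked: MaskedCohort, carry_map: dict[str, str] | None = None) -> CompletedData:
    """Last observation carried backward: a missing *baseline* day takes the
    matching follow-up value."""
    if carry_map is None:
        carry_map = {b: f for f, b in masked.cohort.carry_map().items()}
    return _carry(masked, carry_map, "locb")
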
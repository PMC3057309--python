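"""CSV/JSON serialization.

Dialect: header row of column names (``pid, b1..b7, f1..f7``), one row per
participant, no index column.  Empty cells denote missing values on write;
empty strings and ``NA`` are accepted on read.  Masked cohorts travel with
a sidecar JSON recording the missingness spec (and optionally a second CSV
with the hidden truth for evaluation runs).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .basic import CompletedData
from .cohort import CompleteCohort
from .errors import ValidationError
from .missingness import MaskedCohort, MissingnessSpec

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "read_table_csv",
    "write_masked",
    "read_masked",
    "write_completed",
]

_NA_VALUES = ["", "NA"]


def _read_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    if "pid" not in frame.columns:
        raise ValidationError(f"{path}: expected a 'pid' column")
    return frame.set_index("pid")


def read_table_csv(path) -> pd.DataFrame:
    """Participant-by-variable table (possibly with missing cells)."""
    return _read_csv(path)


def write_table_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=True, na_rep="")


def write_cohort_csv(cohort: CompleteCohort, path) -> None:
    write_table_csv(cohort.data, path)


def read_cohort_csv(path, selected_followup: str | None = None) -> CompleteCohort:
    frame = _read_csv(path)
    if frame.isna().any().any():
        raise ValidationError(f"{path}: a complete cohort may not have missing cells")
    n_days = sum(c.startswith("f") for c in frame.columns)
    if selected_followup is None:
        selected_followup = "f1"
    return CompleteCohort(
        data=frame, selected_followup=selected_followup, n_days_per_wave=n_days
    )


def write_masked(masked: MaskedCohort, path, truth_path=None) -> None:
    """Masked CSV (empty cell = missing) + ``<path>.spec.json`` sidecar."""
    path = Path(path)
    write_table_csv(masked.observed_frame(), path)
    sidecar = {
        "target_variable": masked.spec.target_variable,
        "predictor_variable": masked.spec.predictor_variable,
        "fraction": masked.spec.fraction,
        "mechanism": masked.spec.mechanism,
        "steepness": masked.spec.steepness,
        "seed": masked.spec.seed,
        "realized_fraction": masked.realized_fraction,
        "selected_followup": masked.cohort.selected_followup,
    }
    with open(path.with_suffix(path.suffix + ".spec.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    if truth_path is not None:
        write_table_csv(masked.cohort.data, truth_path)


def read_masked(path, truth_path=None) -> MaskedCohort:
    """Rebuild a MaskedCohort from a masked CSV (+ optional hidden truth).

    Without a truth file the masked values stand in for the truth; the
    mask still records which cells were missing, so imputers work
    normally, but evaluation against the pre-deletion values is only
    possible when the truth CSV is supplied.
    """
    path = Path(path)
    observed = _read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".spec.json")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        spec = MissingnessSpec(
            target_variable=sidecar["target_variable"],
            predictor_variable=sidecar.get("predictor_variable"),
            fraction=sidecar.get("fraction", 0.5),
            mechanism=sidecar.get("mechanism", "MAR_stochastic"),
            steepness=sidecar.get("steepness", 1.5),
            seed=sidecar.get("seed", 0),
        )
        selected = sidecar.get("selected_followup", "f1")
    else:
        incomplete = observed.columns[observed.isna().any()]
        target = incomplete[0] if len(incomplete) else "f1"
        spec = MissingnessSpec(
            target_variable=target, predictor_variable=None, mechanism="MCAR"
        )
        selected = target if str(target).startswith("f") else "f1"
    truth = _read_csv(truth_path) if truth_path is not None else observed.fillna(0)
    n_days = sum(c.startswith("f") for c in observed.columns)
    cohort = CompleteCohort(
        data=truth, selected_followup=selected, n_days_per_wave=n_days
    )
    return MaskedCohort(
        cohort=cohort,
        mask=observed.notna(),
        spec=spec,
        realized_fraction=float(observed[spec.target_variable].isna().mean()),
    )


def write_completed(completed: CompletedData, out_dir, stem: str = "imputed") -> list[Path]:
    """Write one CSV per dataset plus a manifest JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, d in enumerate(completed.datasets, start=1):
        p = out_dir / (f"{stem}.csv" if completed.m == 1 else f"{stem}_{i}.csv")
        write_table_csv(d, p)
        paths.append(p)
    manifest = {
        "method": completed.method_label,
        "m": completed.m,
        "datasets": [p.name for p in paths],
        "provenance": _jsonable(completed.provenance),
    }
    with open(out_dir / f"{stem}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
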
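"""Validity, reliability and coverage evaluation of the nine approaches.

The harness reproduces a three-part benchmark design:

* **Validity** — after a single application of each approach to the masked
  cohort, an independent-samples pooled-variance t test (with Cohen's d)
  compares the completed target variable against the reference (complete)
  variable.  The imputed sample is treated as independent of the reference
  even though they share the observed cases; this mirrors the benchmark
  convention (df = n1 + n2 - 2) and is a fidelity choice, not a
  statistical recommendation.
* **Reliability** — 75 bootstrap resamples (rows drawn with replacement
  from the *masked* cohort) are re-imputed by every approach; the variance
  of the 75 completed-data means measures how stable each approach is.
* **Coverage** — the proportion of those 75 means that fall inside the
  95% t-interval of the reference mean; a joint indicator of validity and
  reliability.

For MI approaches the per-resample mean is the Rubin-pooled mean (the
arithmetic mean of the m dataset means); strip-chart exports use the first
imputed dataset only, following the plotting convention of the benchmark.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .cohort import CohortConfig, generate_cohort
from .errors import (
    CarryError,
    DegenerateDataError,
    SamplerError,
    ValidationError,
)
from .missingness import MaskedCohort, MissingnessSpec, default_spec, induce_mar
from .multiple import MISettings
from .registry import APPROACH_LABELS, StudyMeta, apply_approach

__all__ = [
    "TestResult",
    "CoverageResult",
    "ApproachRow",
    "StudyReport",
    "two_sample_t",
    "coverage",
    "reference_interval",
    "bootstrap_study",
    "run_full_study",
    "run_replicated_study",
]

_APPROACH_FAILURES = (DegenerateDataError, SamplerError, CarryError)


@dataclass(frozen=True)
class TestResult:
    """Independent-samples pooled-variance t test of group 1 vs group 2."""

    t: float
    df: float
    p: float
    cohens_d: float
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CoverageResult:
    coverage_proportion: float
    n_inside: int
    n_total: int
    variance_of_means: float
    reference_ci: tuple[float, float]
    n_failed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["reference_ci"] = list(self.reference_ci)
        return d


def two_sample_t(mean_1, sd_1, n_1, mean_2, sd_2, n_2) -> TestResult:
    """Pooled-variance Student t test from summary statistics.

    ``s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2)``;
    ``t = (m1 - m2) / (s_p sqrt(1/n1 + 1/n2))``; df = n1 + n2 - 2;
    Cohen's d uses the same pooled SD.  Two-sided p.
    """
    if n_1 < 2 or n_2 < 2:
        raise ValidationError("both groups need n >= 2")
    if sd_1 < 0 or sd_2 < 0 or (sd_1 == 0 and sd_2 == 0):
        raise ValidationError("sds must be >= 0 and not both zero")
    df = n_1 + n_2 - 2
    sp2 = ((n_1 - 1) * sd_1**2 + (n_2 - 1) * sd_2**2) / df
    sp = math.sqrt(sp2)
    diff = mean_1 - mean_2
    t = diff / (sp * math.sqrt(1.0 / n_1 + 1.0 / n_2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(
        t=float(t),
        df=float(df),
        p=float(p),
        cohens_d=float(diff / sp),
        mean_1=float(mean_1),
        sd_1=float(sd_1),
        n_1=int(n_1),
        mean_2=float(mean_2),
        sd_2=float(sd_2),
        n_2=int(n_2),
    )


def coverage(bootstrap_means: Sequence[float], reference_ci) -> CoverageResult:
    """Proportion of means inside the closed interval ``reference_ci``.

    NaN entries (failed resamples) are excluded from the denominator and
    reported in ``n_failed``.
    """
    lo, hi = float(reference_ci[0]), float(reference_ci[1])
    if lo > hi:
        raise ValidationError("reference_ci must satisfy low <= high")
    arr = np.asarray(bootstrap_means, float)
    if arr.size == 0:
        raise ValidationError("empty bootstrap means")
    ok = np.isfinite(arr)
    vals = arr[ok]
    if vals.size == 0:
        raise ValidationError("all bootstrap means failed")
    inside = int(((vals >= lo) & (vals <= hi)).sum())
    return CoverageResult(
        coverage_proportion=inside / vals.size,
        n_inside=inside,
        n_total=int(vals.size),
        variance_of_means=float(vals.var(ddof=1)) if vals.size > 1 else float("nan"),
        reference_ci=(lo, hi),
        n_failed=int((~ok).sum()),
    )


def reference_interval(values: Sequence[float], level: float = 0.95):
    """t-based CI of the mean: ``mean +/- t(n-1, (1+level)/2) * sd / sqrt(n)``."""
    v = np.asarray(values, float)
    n = v.size
    if n < 2:
        raise ValidationError("need n >= 2 for a reference interval")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / math.sqrt(n)
    return mean, sd, (mean - half, mean + half)


def _target_mean(datasets: list[np.ndarray], target: int) -> float:
    """Per-application summary: Rubin-pooled mean for MI (= mean of the m
    dataset means), the single dataset's mean otherwise."""
    return float(np.mean([d[:, target].mean() for d in datasets]))


def bootstrap_study(
    masked: MaskedCohort,
    approaches: Sequence[str] | None = None,
    B: int = 75,
    seed: int = 0,
    mi_settings: MISettings = MISettings(),
) -> dict[str, np.ndarray]:
    """B bootstrap resamples of the masked cohort, re-imputed by every
    approach; returns per-approach arrays of B completed-data target means.

    All approaches see the same resamples; per-(resample, approach) RNG
    streams are derived deterministically from ``seed``, so a rerun with
    the same master seed is bit-identical.  An approach failing on a
    resample (e.g. zero complete cases) yields NaN for that entry.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    labels = list(APPROACH_LABELS) if approaches is None else list(approaches)
    frame = masked.observed_frame()
    X = frame.to_numpy(float)
    miss = frame.isna().to_numpy()
    meta = StudyMeta.from_masked(masked)
    n = X.shape[0]
    out = {lab: np.full(B, np.nan) for lab in labels}
    order = {lab: APPROACH_LABELS.index(lab) for lab in labels}
    for b in range(B):
        rows = np.random.default_rng([seed, b]).integers(0, n, size=n)
        Xb = X[rows]
        missb = miss[rows]
        for lab in labels:
            rng = np.random.default_rng([seed, b, order[lab]])
            try:
                datasets = apply_approach(lab, Xb, missb, meta, rng, mi_settings)
            except _APPROACH_FAILURES:
                continue
            out[lab][b] = _target_mean(datasets, meta.target)
    return out


@dataclass
class ApproachRow:
    """One benchmark row: single-shot summary + validity test + coverage."""

    label: str
    mean: float
    sd: float
    n: int
    pooled_mean: float
    m: int
    test: TestResult | None
    coverage: CoverageResult | None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mean": self.mean,
            "sd": self.sd,
            "n": self.n,
            "pooled_mean": self.pooled_mean,
            "m": self.m,
            "test": self.test.to_dict() if self.test else None,
            "coverage": self.coverage.to_dict() if self.coverage else None,
            "error": self.error,
        }


@dataclass
class StudyReport:
    """Full study output: reference statistics, one row per approach, the
    bootstrap means behind the coverage numbers, and strip-chart data."""

    reference_mean: float
    reference_sd: float
    reference_n: int
    reference_ci: tuple[float, float]
    rows: list[ApproachRow]
    bootstrap_means: dict[str, np.ndarray]
    figure1_observations: pd.DataFrame
    settings: dict
    realized_missing_fraction: float
    n_complete_cases: int

    def row(self, label: str) -> ApproachRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def table2_frame(self) -> pd.DataFrame:
        recs = [
            {
                "method": "reference",
                "mean": self.reference_mean,
                "sd": self.reference_sd,
                "n": self.reference_n,
                "t": 0.0,
                "df": 2 * self.reference_n - 2,
                "p": 1.0,
                "cohens_d": 0.0,
                "pooled_mean": self.reference_mean,
            }
        ]
        for r in self.rows:
            recs.append(
                {
                    "method": r.label,
                    "mean": r.mean,
                    "sd": r.sd,
                    "n": r.n,
                    "t": r.test.t if r.test else float("nan"),
                    "df": r.test.df if r.test else float("nan"),
                    "p": r.test.p if r.test else float("nan"),
                    "cohens_d": r.test.cohens_d if r.test else float("nan"),
                    "pooled_mean": r.pooled_mean,
                }
            )
        return pd.DataFrame.from_records(recs)

    def table3_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            cov = r.coverage
            recs.append(
                {
                    "method": r.label,
                    "coverage_proportion": cov.coverage_proportion if cov else float("nan"),
                    "variance_of_means": cov.variance_of_means if cov else float("nan"),
                    "n_inside": cov.n_inside if cov else 0,
                    "n_total": cov.n_total if cov else 0,
                }
            )
        return pd.DataFrame.from_records(recs)

    def figure2_frame(self) -> pd.DataFrame:
        recs = []
        for lab, means in self.bootstrap_means.items():
            for b, v in enumerate(means):
                recs.append({"method": lab, "resample": b, "mean": v})
        return pd.DataFrame.from_records(recs)

    def to_json(self, path=None) -> str:
        payload = {
            "package_version": _pkg_version,
            "reference": {
                "mean": self.reference_mean,
                "sd": self.reference_sd,
                "n": self.reference_n,
                "ci": list(self.reference_ci),
            },
            "realized_missing_fraction": self.realized_missing_fraction,
            "n_complete_cases": self.n_complete_cases,
            "settings": self.settings,
            "rows": [r.to_dict() for r in self.rows],
            "bootstrap_means": {k: list(map(float, v)) for k, v in self.bootstrap_means.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _derive_seeds(master_seed: int, k: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(k, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def run_full_study(
    cohort_config: CohortConfig | None = None,
    missingness_spec: MissingnessSpec | None = None,
    approaches: Sequence[str] | None = None,
    B: int = 75,
    mi_settings: MISettings = MISettings(),
    master_seed: int = 0,
) -> StudyReport:
    """End-to-end study: generate reference cohort, induce missingness,
    apply every approach once (validity), bootstrap B resamples
    (reliability + coverage), and assemble the report."""
    labels = list(APPROACH_LABELS) if approaches is None else list(approaches)
    seeds = _derive_seeds(master_seed, 4)
    config = cohort_config if cohort_config is not None else CohortConfig()
    config = replace(config, seed=seeds[0])
    cohort = generate_cohort(config)

    ref_values = cohort.data[cohort.selected_followup]
    ref_mean, ref_sd, ref_ci = reference_interval(ref_values)
    n = cohort.n_participants

    if missingness_spec is None:
        spec = default_spec(cohort, fraction=0.5, seed=seeds[1])
    else:
        spec = replace(missingness_spec, seed=seeds[1])
    masked = induce_mar(cohort, spec)

    frame = masked.observed_frame()
    X = frame.to_numpy(float)
    miss = frame.isna().to_numpy()
    meta = StudyMeta.from_masked(masked)

    rows: list[ApproachRow] = []
    figure1 = {"reference": ref_values.to_numpy(float)}
    for lab in labels:
        rng = np.random.default_rng([seeds[2], APPROACH_LABELS.index(lab)])
        try:
            datasets = apply_approach(lab, X, miss, meta, rng, mi_settings)
        except _APPROACH_FAILURES as exc:
            rows.append(
                ApproachRow(
                    label=lab, mean=float("nan"), sd=float("nan"), n=0,
                    pooled_mean=float("nan"), m=0, test=None, coverage=None,
                    error=str(exc),
                )
            )
            continue
        first = datasets[0][:, meta.target]
        mean_first = float(first.mean())
        sd_first = float(first.std(ddof=1))
        n_first = int(first.size)
        pooled = _target_mean(datasets, meta.target)
        test = two_sample_t(mean_first, sd_first, n_first, ref_mean, ref_sd, n)
        rows.append(
            ApproachRow(
                label=lab, mean=mean_first, sd=sd_first, n=n_first,
                pooled_mean=pooled, m=len(datasets), test=test, coverage=None,
            )
        )
        if lab != "complete_cases":
            figure1[lab] = first
        else:
            pad = np.full(n, np.nan)
            pad[: len(first)] = first
            figure1[lab] = pad

    boot = bootstrap_study(
        masked, approaches=labels, B=B, seed=seeds[3], mi_settings=mi_settings
    )
    for r in rows:
        if r.error is None:
            r.coverage = coverage(boot[r.label], ref_ci)

    fig1 = pd.DataFrame(figure1)
    settings = {
        "cohort_config": {**config.__dict__},
        "missingness_spec": {**spec.__dict__},
        "approaches": labels,
        "B": B,
        "mi_settings": {**mi_settings.__dict__},
        "master_seed": master_seed,
        "derived_seeds": seeds,
    }
    return StudyReport(
        reference_mean=ref_mean,
        reference_sd=ref_sd,
        reference_n=n,
        reference_ci=ref_ci,
        rows=rows,
        bootstrap_means=boot,
        figure1_observations=fig1,
        settings=settings,
        realized_missing_fraction=masked.realized_fraction,
        n_complete_cases=masked.n_complete_cases,
    )


def run_replicated_study(
    n_replicates: int = 50,
    master_seed: int = 0,
    cohort_config: CohortConfig | None = None,
    approaches: Sequence[str] | None = None,
    B: int = 75,
    mi_settings: MISettings = MISettings(),
) -> pd.DataFrame:
    """Repeat the full study ``n_replicates`` times with independent seeds.

    Returns one row per (replicate, approach) with the single-shot mean,
    the coverage proportion, the variance of bootstrapped means, and
    whether the approach attained the replicate's maximum coverage (ties
    count as attaining it).
    """
    recs = []
    for rep in range(n_replicates):
        report = run_full_study(
            cohort_config=cohort_config,
            approaches=approaches,
            B=B,
            mi_settings=mi_settings,
            master_seed=int(np.random.SeedSequence([master_seed, rep]).generate_state(1)[0] % (2**31)),
        )
        covs = {
            r.label: r.coverage.coverage_proportion
            for r in report.rows
            if r.coverage is not None
        }
        top = max(covs.values())
        for r in report.rows:
            cov = covs.get(r.label, float("nan"))
            recs.append(
                {
                    "replicate": rep,
                    "method": r.label,
                    "mean": r.mean,
                    "pooled_mean": r.pooled_mean,
                    "reference_mean": report.reference_mean,
                    "coverage": cov,
                    "variance_of_means": (
                        r.coverage.variance_of_means if r.coverage else float("nan")
                    ),
                    "attains_max_coverage": bool(cov == top),
                }
            )
    return pd.DataFrame.from_records(recs)
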
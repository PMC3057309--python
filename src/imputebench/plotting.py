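"""Optional strip-chart helpers mirroring the benchmark's two figures.

Requires matplotlib (install the ``plot`` extra).  Jitter here is purely
cosmetic, to keep equal values from overplotting.
"""

from __future__ import annotations

import numpy as np

from .evaluation import StudyReport

__all__ = ["strip_chart", "bootstrap_chart"]


def _jitter(rng, n, width=0.18):
    return rng.uniform(-width, width, size=n)


def strip_chart(report: StudyReport, ax=None, seed: int = 0):
    """Per-approach completed observations (first MI dataset only), with the
    reference column first."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(10, 5))
    rng = np.random.default_rng(seed)
    frame = report.figure1_observations
    for i, col in enumerate(frame.columns):
        y = frame[col].dropna().to_numpy()
        ax.plot(i + _jitter(rng, len(y)), y, "o", ms=3, alpha=0.5)
    ax.set_xticks(range(len(frame.columns)))
    ax.set_xticklabels(frame.columns, rotation=45, ha="right")
    ax.set_ylabel("drinks per day (completed data)")
    return ax


def bootstrap_chart(report: StudyReport, ax=None, seed: int = 0):
    """Bootstrap means per approach with the reference 95% CI band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(10, 5))
    rng = np.random.default_rng(seed)
    labels = list(report.bootstrap_means)
    for i, lab in enumerate(labels):
        y = np.asarray(report.bootstrap_means[lab], float)
        y = y[np.isfinite(y)]
        ax.plot(i + _jitter(rng, len(y)), y, "k.", ms=4, alpha=0.6)
        ax.plot([i], [y.mean()], "wo", mec="k", ms=8, zorder=3)
    lo, hi = report.reference_ci
    ax.axhline(lo, ls="--", c="gray")
    ax.axhline(hi, ls="--", c="gray")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("bootstrapped mean (drinks per day)")
    return ax
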
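"""Cohort-level normalization and distribution summary of SNAVF values.

Raw SNAVF values are positive ratios whose absolute scale depends on
acquisition conditions, so a cohort is summarized on a normalized
scale balanced by the average: n_i = (v_i - mean) / mean, which has
mean exactly 0 and is invariant to rescaling every input by a common
positive factor.  A z-score alternative is available.

Quartiles follow the lower/upper-half-median rule (Moore-McCabe): Q2
is the median; Q1 and Q3 are the medians of the halves below and above
it (the overall median excluded when the count is odd); the "fourth
quartile" is reported as the maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSummary",
    "normalize_snavf",
    "quartile_summary",
    "cohort_summary",
    "implied_mean_raw",
    "load_snavf_csv",
]


def normalize_snavf(values, method: str = "relative") -> np.ndarray:
    """Balance a list of positive SNAVF ratios by the cohort average.

    ``"relative"`` (default): (v - mean) / mean — relative deviation
    from the mean.  ``"zscore"``: (v - mean) / std.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty input")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean of input values is zero")
    if method == "relative":
        return (v - mean) / mean
    if method == "zscore":
        std = v.std(ddof=1)
        if std == 0:
            return np.zeros_like(v)
        return (v - mean) / std
    raise ValueError(f"unknown normalization method {method!r}")


def quartile_summary(values) -> tuple[float, float, float, float]:
    """(Q1, Q2, Q3, Q4) by half-medians, with Q4 the maximum.

    Q2 is the overall median.  Q1 is the middle number between the
    minimum and the median — the median of the lower half, excluding
    the overall median for odd counts; Q3 likewise for the upper half.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size
    if n < 4:
        raise ValueError(f"need at least 4 values; got {n}")
    q2 = float(np.median(v))
    lower = v[: n // 2]
    upper = v[(n + 1) // 2 :]
    return float(np.median(lower)), q2, float(np.median(upper)), float(v[-1])


@dataclass
class CohortSummary:
    """Normalized SNAVF distribution of one cohort."""

    n_subjects: int
    normalized_values: np.ndarray
    mean_raw: float
    median_norm: float
    q1: float
    q2: float
    q3: float
    q4_max: float
    method: str = "relative"
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "n_subjects": self.n_subjects,
            "mean_raw_snavf": self.mean_raw,
            "normalization": self.method,
            "median_norm": self.median_norm,
            "quartiles": {"q1": self.q1, "q2": self.q2, "q3": self.q3,
                          "q4_max": self.q4_max},
            **self.meta,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def histogram_png(self, path, bins: int = 20) -> Path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(self.normalized_values, bins=bins, color="#3465a4",
                edgecolor="white")
        ax.set_xlabel("normalized SNAVF")
        ax.set_ylabel("recordings")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)


def cohort_summary(raw_values, method: str = "relative") -> CohortSummary:
    """Normalize raw SNAVF ratios and summarize their distribution."""
    raw = np.asarray(raw_values, dtype=np.float64)
    if np.any(raw <= 0):
        raise ValueError("raw SNAVF values must be positive ratios")
    norm = normalize_snavf(raw, method=method)
    q1, q2, q3, q4 = quartile_summary(norm)
    return CohortSummary(
        n_subjects=raw.size,
        normalized_values=norm,
        mean_raw=float(raw.mean()),
        median_norm=float(np.median(norm)),
        q1=q1,
        q2=q2,
        q3=q3,
        q4_max=q4,
        method=method,
    )


def implied_mean_raw(raw_max: float, normalized_max: float) -> float:
    """Back out the cohort's raw mean from its raw maximum and the
    maximum on the relative-deviation scale.

    Under n = (v - mean)/mean the maxima satisfy
    ``norm_max = raw_max/mean - 1``, so ``mean = raw_max / (1 + norm_max)``.
    A consistency aid when only published summary numbers are at hand.
    """
    if normalized_max <= -1:
        raise ValueError("normalized maximum must exceed -1")
    return raw_max / (1.0 + normalized_max)


def load_snavf_csv(path) -> pd.DataFrame:
    """Read per-recording SNAVF values (columns: subject_id, recording_id,
    snavf)."""
    df = pd.read_csv(path)
    if "snavf" not in df.columns:
        raise ValueError(f"{path}: expected a 'snavf' column; got {list(df.columns)}")
    return df
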
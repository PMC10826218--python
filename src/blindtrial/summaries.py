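"""Descriptive statistics and secondary-outcome contrasts.

Feasibility trials report descriptive statistics only: medians with
interquartile ranges for quantitative data, counts and percentages for
categorical data, and between-group mean differences with unequal-variance
(Welch) confidence intervals — no formal hypothesis tests. The Welch
interval is computed from group summaries (mean, SD, n), so published
summary tables suffice as input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "MeanDifference",
    "welch_mean_diff",
    "describe_numeric",
    "describe_categorical",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation and size of one group (e.g. ROM in degrees)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("interval estimation needs n >= 2 per group")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        return cls(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


@dataclass(frozen=True)
class MeanDifference:
    md: float
    ci_lower: float
    ci_upper: float
    df: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_lower - 1e-9 <= self.md <= self.ci_upper + 1e-9:
            raise ValueError("interval must bracket the mean difference")


def welch_mean_diff(g1: GroupSummary, g2: GroupSummary, level: float = 0.95) -> MeanDifference:
    """Mean difference g1 - g2 with a Welch–Satterthwaite t interval.

    Degenerate (zero-width) when both SDs are zero.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    md = g1.mean - g2.mean
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    se2 = v1 + v2
    if se2 == 0:
        return MeanDifference(md, md, md, df=float(g1.n + g2.n - 2), level=level)
    df = se2**2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    half = stats.t.ppf(0.5 + level / 2, df) * math.sqrt(se2)
    return MeanDifference(md, md - half, md + half, df=float(df), level=level)


def describe_numeric(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median and interquartile range (25th, 75th percentile, linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("describe_numeric needs at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def describe_categorical(values: Sequence) -> pd.DataFrame:
    """Per-level counts and percentages (of total), as a tidy frame."""
    s = pd.Series(list(values))
    if s.empty:
        raise ValueError("describe_categorical needs at least one value")
    counts = s.value_counts(sort=False)
    return pd.DataFrame({
        "level": counts.index.astype(str),
        "count": counts.to_numpy(),
        "percentage": counts.to_numpy() / len(s) * 100.0,
    }).reset_index(drop=True)
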
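"""Bang and James blinding indices for two-arm sham-controlled trials.

Blinding success is assessed by asking each respondent (a trial participant,
or an outcome assessor judging a participant) to what extent they believe the
participant received the active or the control intervention, on a five-level
instrument: strongly/somewhat active, don't know, somewhat/strongly control.

Two standard indices summarise these responses:

* The Bang blinding index is arm-specific,
  ``BI = p_correct - p_incorrect = (r_c - r_i) / n``,
  ranging from -1 (complete opposite perception) through 0 (balanced,
  "random guessing") to 1 (complete correct perception). Its variance is
  ``[p_c + p_i - (p_c - p_i)^2] / n`` and confidence intervals are Wald
  intervals on that variance. The two arm indices can be summed
  (``BI_active + BI_control``) into a study-level index whose variance is
  the sum of the arm variances.

* The James blinding index is study-level on [0, 1]: 1 is complete
  ambivalence (everyone answers "don't know"), values near 0.5 are
  consistent with random guessing, and values below 0.5 suggest unblinding.
  It is computed here as ``BI_J = [1 + P_dk + sum_ij w_ij p_ij] / 2`` where
  ``P_dk`` is the don't-know proportion, ``p_ij`` the joint proportions of
  the four directed guess categories, and ``w_ij`` signed weights
  (-1 strongly correct, -0.5 somewhat correct, +0.5 somewhat incorrect,
  +1 strongly incorrect).

An arm with no guessers at all (every response "don't know") makes the Bang
index mathematically undefinable; this is reported through an ``undefined``
flag and NaN sentinels rather than coerced to 0.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ARMS",
    "GuessCategory",
    "ArmResponseTable",
    "CollapsedCounts",
    "BlindingEstimate",
    "JamesWeights",
    "round_half_away",
    "collapse_responses",
    "bang_point",
    "bang_variance",
    "wald_ci",
    "bang_estimate",
    "bang_estimate_from_counts",
    "summed_bang",
    "james_point",
    "james_ci",
    "james_estimate",
    "respondent_scores",
    "classify_blinding",
]

ARMS = ("active", "control")


class GuessCategory(str, enum.Enum):
    """Five-level response to "which intervention do you think was received?"."""

    STRONGLY_ACTIVE = "strongly_active"
    SOMEWHAT_ACTIVE = "somewhat_active"
    DONT_KNOW = "dont_know"
    SOMEWHAT_CONTROL = "somewhat_control"
    STRONGLY_CONTROL = "strongly_control"

    @property
    def direction(self) -> str | None:
        """Guessed arm ("active"/"control"), or None for don't know."""
        if self in (GuessCategory.STRONGLY_ACTIVE, GuessCategory.SOMEWHAT_ACTIVE):
            return "active"
        if self in (GuessCategory.STRONGLY_CONTROL, GuessCategory.SOMEWHAT_CONTROL):
            return "control"
        return None

    @property
    def strength(self) -> str | None:
        """"strong" or "somewhat" for directed guesses, None for don't know."""
        if self in (GuessCategory.STRONGLY_ACTIVE, GuessCategory.STRONGLY_CONTROL):
            return "strong"
        if self in (GuessCategory.SOMEWHAT_ACTIVE, GuessCategory.SOMEWHAT_CONTROL):
            return "somewhat"
        return None


def _check_arm(arm: str) -> str:
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    return arm


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed trial reports)."""
    if math.isnan(x):
        return x
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class ArmResponseTable:
    """Five-category guess counts for the respondents of one actual arm."""

    arm: str
    strongly_active: int = 0
    somewhat_active: int = 0
    dont_know: int = 0
    somewhat_control: int = 0
    strongly_control: int = 0

    def __post_init__(self) -> None:
        _check_arm(self.arm)
        for cat in GuessCategory:
            c = getattr(self, cat.value)
            if not isinstance(c, (int, np.integer)) or c < 0:
                raise ValueError(f"count {cat.value}={c!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return sum(self.count(cat) for cat in GuessCategory)

    def count(self, category: GuessCategory) -> int:
        return int(getattr(self, GuessCategory(category).value))

    @classmethod
    def from_responses(cls, arm: str, responses: Iterable[GuessCategory | str]) -> "ArmResponseTable":
        counts = {cat.value: 0 for cat in GuessCategory}
        for r in responses:
            counts[GuessCategory(r).value] += 1
        return cls(arm=arm, **counts)

    def to_responses(self) -> list[GuessCategory]:
        """Expand back to one response per respondent (deterministic order)."""
        out: list[GuessCategory] = []
        for cat in GuessCategory:
            out.extend([cat] * self.count(cat))
        return out


@dataclass(frozen=True)
class CollapsedCounts:
    """Correct/incorrect/don't-know counts after merging strength levels."""

    r_correct: int
    r_incorrect: int
    r_dontknow: int

    def __post_init__(self) -> None:
        if min(self.r_correct, self.r_incorrect, self.r_dontknow) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.r_correct + self.r_incorrect + self.r_dontknow

    def __add__(self, other: "CollapsedCounts") -> "CollapsedCounts":
        return CollapsedCounts(
            self.r_correct + other.r_correct,
            self.r_incorrect + other.r_incorrect,
            self.r_dontknow + other.r_dontknow,
        )


@dataclass(frozen=True)
class BlindingEstimate:
    """A blinding index with its variance and two-sided confidence interval.

    ``undefined`` marks estimates the data cannot support (Bang index with no
    guessers); point, variance and CI then carry NaN sentinels.
    """

    index_type: str  # bang_arm | bang_summed | james
    point: float
    variance: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95
    n: int = 0
    undefined: bool = False

    def __post_init__(self) -> None:
        if self.index_type not in ("bang_arm", "bang_summed", "james"):
            raise ValueError(f"unknown index_type {self.index_type!r}")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.undefined:
            if not (math.isnan(self.point) and math.isnan(self.ci_lower)):
                raise ValueError("undefined estimates must carry NaN sentinels")
        else:
            eps = 1e-9
            if not (self.ci_lower - eps <= self.point <= self.ci_upper + eps):
                raise ValueError("confidence interval must bracket the point estimate")


@dataclass(frozen=True)
class JamesWeights:
    """Signed cell weights of the James index; antisymmetric by default."""

    strong_correct: float = -1.0
    somewhat_correct: float = -0.5
    somewhat_incorrect: float = 0.5
    strong_incorrect: float = 1.0


DEFAULT_JAMES_WEIGHTS = JamesWeights()


def collapse_responses(table: ArmResponseTable) -> CollapsedCounts:
    """Merge strength levels: a guess is correct iff its direction matches the arm."""
    correct = incorrect = 0
    for cat in GuessCategory:
        if cat.direction is None:
            continue
        if cat.direction == table.arm:
            correct += table.count(cat)
        else:
            incorrect += table.count(cat)
    return CollapsedCounts(correct, incorrect, table.count(GuessCategory.DONT_KNOW))


def bang_point(c: CollapsedCounts) -> float:
    """Bang blinding index point estimate (correct - incorrect)/n.

    NaN when nobody ventured a guess (mathematically undefinable).
    """
    if c.n == 0:
        raise ValueError("empty group: n must be at least 1")
    if c.r_correct + c.r_incorrect == 0:
        return float("nan")
    return (c.r_correct - c.r_incorrect) / c.n


def bang_variance(c: CollapsedCounts) -> float:
    """Plug-in variance [p_c + p_i - (p_c - p_i)^2] / n; NaN with no guessers."""
    if c.n == 0:
        raise ValueError("empty group: n must be at least 1")
    if c.r_correct + c.r_incorrect == 0:
        return float("nan")
    p_c = c.r_correct / c.n
    p_i = c.r_incorrect / c.n
    return max(0.0, (p_c + p_i - (p_c - p_i) ** 2) / c.n)


def wald_ci(point: float, variance: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-quantile interval point ± z·sqrt(variance); NaN inputs propagate.

    The interval is deliberately not truncated to the index range: a summed
    index near the boundary can have a bound beyond ±1.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if math.isnan(point) or math.isnan(variance):
        return (float("nan"), float("nan"))
    if variance < 0:
        raise ValueError("variance must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(variance)
    return (point - half, point + half)


def bang_estimate_from_counts(c: CollapsedCounts, level: float = 0.95,
                              index_type: str = "bang_arm") -> BlindingEstimate:
    point = bang_point(c)
    variance = bang_variance(c)
    lo, hi = wald_ci(point, variance, level)
    return BlindingEstimate(
        index_type=index_type,
        point=point,
        variance=variance,
        ci_lower=lo,
        ci_upper=hi,
        level=level,
        n=c.n,
        undefined=math.isnan(point),
    )


def bang_estimate(table: ArmResponseTable, level: float = 0.95) -> BlindingEstimate:
    """Arm-level Bang index from a five-category response table."""
    return bang_estimate_from_counts(collapse_responses(table), level)


def summed_bang(active: BlindingEstimate, control: BlindingEstimate,
                rounding_convention: bool = True) -> BlindingEstimate:
    """Study-level summed Bang index BI_active + BI_control.

    With ``rounding_convention`` (default) the summands are first rounded to
    two decimals, matching how trial reports print and then sum the arm
    indices; the variance is always the exact sum of arm variances. Either
    input undefined makes the sum undefined.
    """
    level = active.level
    if control.level != level:
        raise ValueError("arm estimates must share a confidence level")
    n = active.n + control.n
    if active.undefined or control.undefined:
        nan = float("nan")
        return BlindingEstimate("bang_summed", nan, nan, nan, nan, level, n, undefined=True)
    if rounding_convention:
        point = round_half_away(active.point) + round_half_away(control.point)
    else:
        point = active.point + control.point
    variance = active.variance + control.variance
    lo, hi = wald_ci(point, variance, level)
    return BlindingEstimate("bang_summed", point, variance, lo, hi, level, n)


def _cell_weight(arm: str, category: GuessCategory, weights: JamesWeights) -> float:
    direction, strength = category.direction, category.strength
    if direction is None:
        return 0.0
    correct = direction == arm
    if strength == "strong":
        return weights.strong_correct if correct else weights.strong_incorrect
    return weights.somewhat_correct if correct else weights.somewhat_incorrect


def respondent_scores(records: Sequence[tuple[str, GuessCategory | str]],
                      weights: JamesWeights = DEFAULT_JAMES_WEIGHTS) -> np.ndarray:
    """Per-respondent James scores s_r = (1 + 1[don't know] + w_r) / 2.

    The James index is the mean of these scores, which makes bootstrap
    resampling over respondents a resampled mean.
    """
    scores = []
    for arm, guess in records:
        _check_arm(arm)
        cat = GuessCategory(guess)
        dk = 1.0 if cat is GuessCategory.DONT_KNOW else 0.0
        scores.append((1.0 + dk + _cell_weight(arm, cat, weights)) / 2.0)
    return np.asarray(scores, dtype=float)


def _records_from_tables(active: ArmResponseTable, control: ArmResponseTable
                         ) -> list[tuple[str, GuessCategory]]:
    if active.arm != "active" or control.arm != "control":
        raise ValueError("expected one active-arm and one control-arm table")
    recs = [("active", g) for g in active.to_responses()]
    recs += [("control", g) for g in control.to_responses()]
    return recs


def james_point(active: ArmResponseTable, control: ArmResponseTable,
                weights: JamesWeights = DEFAULT_JAMES_WEIGHTS) -> float:
    """Study-level James index pooled over both arms."""
    records = _records_from_tables(active, control)
    if not records:
        raise ValueError("empty pooled table: James index needs at least one respondent")
    return float(respondent_scores(records, weights).mean())


def james_ci(records: Sequence[tuple[str, GuessCategory | str]],
             level: float = 0.95, n_resamples: int = 10_000,
             seed: int | np.random.Generator | None = None,
             weights: JamesWeights = DEFAULT_JAMES_WEIGHTS) -> tuple[float, float]:
    """Percentile-bootstrap CI for the James index, resampling respondents.

    Constant data yield a degenerate interval at the point estimate.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_resamples < 100:
        warnings.warn("fewer than 100 bootstrap resamples gives unstable intervals",
                      stacklevel=2)
    scores = respondent_scores(records, weights)
    n = scores.size
    if n == 0:
        raise ValueError("empty records")
    if np.ptp(scores) == 0:
        v = float(scores[0])
        return (v, v)
    if n < 2:
        raise ValueError("bootstrap needs at least 2 respondents unless data are constant")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    means = scores[idx].mean(axis=1)
    alpha = 1 - level
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


def james_estimate(active: ArmResponseTable, control: ArmResponseTable,
                   level: float = 0.95, n_resamples: int = 10_000,
                   seed: int | np.random.Generator | None = None,
                   weights: JamesWeights = DEFAULT_JAMES_WEIGHTS) -> BlindingEstimate:
    """James point estimate with a bootstrap percentile CI."""
    records = _records_from_tables(active, control)
    point = james_point(active, control, weights)
    lo, hi = james_ci(records, level=level, n_resamples=n_resamples, seed=seed,
                      weights=weights)
    scores = respondent_scores(records, weights)
    variance = float(scores.var(ddof=1) / scores.size) if scores.size > 1 else 0.0
    # a bootstrap interval can (rarely) exclude the plug-in point; clamp for the contract
    lo, hi = min(lo, point), max(hi, point)
    return BlindingEstimate("james", point, variance, lo, hi, level,
                            n=len(records))


def classify_blinding(e: BlindingEstimate) -> str:
    """Operational adequacy call for a blinding estimate.

    Arm-level Bang: adequate iff the point lies in [-0.2, 0.2] (closed).
    Summed Bang: adequate iff the point lies in [-0.3, 0.3].
    James: inadequate blinding is suggested only when the CI upper bound
    falls below 0.5. Undefined estimates are undetermined.
    """
    if e.undefined:
        return "undetermined"
    if e.index_type == "bang_arm":
        return "adequate" if -0.2 <= e.point <= 0.2 else "not_adequate"
    if e.index_type == "bang_summed":
        return "adequate" if -0.3 <= e.point <= 0.3 else "not_adequate"
    return "not_adequate" if e.ci_upper < 0.5 else "adequate"
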
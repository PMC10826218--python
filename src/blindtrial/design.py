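"""Precision-based design for the Bang blinding index.

With a sample size fixed by circumstance (e.g. a course cohort), a blinding
feasibility study is sized by the precision of the index rather than by the
power of a test: the design quantity is the half-width of the Wald
confidence interval, z * sqrt([p_c + p_i - (p_c - p_i)^2] / n), under an
assumed guess behaviour (p_c correct, p_i incorrect, the rest "don't
know"). The variance numerator is maximal at p_c = p_i = 0.5, so that
assumption gives the conservative (widest) interval for a given n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["PrecisionAssumption", "ci_halfwidth", "required_n"]


def _variance_numerator(p_correct: float, p_incorrect: float) -> float:
    if p_correct < 0 or p_incorrect < 0 or p_correct + p_incorrect > 1 + 1e-12:
        raise ValueError("need p_correct, p_incorrect >= 0 with sum <= 1")
    return p_correct + p_incorrect - (p_correct - p_incorrect) ** 2


def ci_halfwidth(n: int, p_correct: float = 0.5, p_incorrect: float = 0.5,
                 level: float = 0.95) -> float:
    """Wald CI half-width of the Bang index at sample size ``n``.

    Monotone decreasing in n: halfwidth * sqrt(n) is constant for fixed
    response behaviour.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return z * math.sqrt(max(0.0, _variance_numerator(p_correct, p_incorrect)) / n)


def required_n(target_halfwidth: float, p_correct: float = 0.5,
               p_incorrect: float = 0.5, level: float = 0.95) -> int:
    """Smallest n whose CI half-width does not exceed the target.

    A zero-variance assumption is met by any sample; returns 1.
    """
    if target_halfwidth <= 0:
        raise ValueError("target_halfwidth must be positive")
    v = _variance_numerator(p_correct, p_incorrect)
    if v <= 0:
        return 1
    z = stats.norm.ppf(0.5 + level / 2)
    n = max(1, math.ceil(z * z * v / target_halfwidth**2 - 1e-12))
    # guard the ceil against floating-point edge cases
    while ci_halfwidth(n, p_correct, p_incorrect, level) > target_halfwidth + 1e-15:
        n += 1
    while n > 1 and ci_halfwidth(n - 1, p_correct, p_incorrect, level) <= target_halfwidth + 1e-15:
        n -= 1
    return n


@dataclass(frozen=True)
class PrecisionAssumption:
    """Assumed guess behaviour and sample size for a precision calculation."""

    p_correct: float
    p_incorrect: float
    n: int
    level: float = 0.95

    def __post_init__(self) -> None:
        _variance_numerator(self.p_correct, self.p_incorrect)
        if self.n < 1:
            raise ValueError("n must be at least 1")

    def halfwidth(self) -> float:
        return ci_halfwidth(self.n, self.p_correct, self.p_incorrect, self.level)
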
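"""Exact (Clopper–Pearson) binomial confidence intervals and their
inversion to minimal sample sizes.

The non-comparative design of a diagnostic accuracy study fixes a floor
on the lower confidence limit of an accuracy proportion (PPV, NPV, Se or
Sp) and asks for the smallest number of patients at which that floor is
met, assuming a point estimate for the proportion.  This module provides
the exact interval, the midpoint heuristic for choosing the point
estimate, and the inversion search.

All public functions speak percentages at the interface where the
clinical convention does (metric floors, point estimates); probabilities
in [0, 1] are used internally and for confidence levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .errors import InvalidInputError, NotAchievableError

__all__ = [
    "BinomialObservation",
    "ConfidenceInterval",
    "clopper_pearson_ci",
    "midpoint_estimate",
    "min_n_for_lower_bound",
    "round_half_up",
]

DEFAULT_SEARCH_MAX = 100_000


@dataclass(frozen=True)
class BinomialObservation:
    """Successes out of trials — the count pair behind every accuracy
    proportion (e.g. true positives out of positive calls for PPV)."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials <= 0:
            raise InvalidInputError("trials must be a positive count")
        if not 0 <= self.successes <= self.trials:
            raise InvalidInputError(
                f"successes must lie in [0, trials]; got "
                f"{self.successes}/{self.trials}"
            )

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


@dataclass(frozen=True)
class ConfidenceInterval:
    """Two-sided interval for a proportion at a given confidence level."""

    level: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise InvalidInputError("confidence level must lie in (0, 1)")
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise InvalidInputError(
                f"interval bounds must satisfy 0 <= lower <= upper <= 1; "
                f"got ({self.lower}, {self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def clopper_pearson_ci(obs: BinomialObservation, level: float = 0.95
                       ) -> ConfidenceInterval:
    """Exact two-sided Clopper–Pearson interval for a binomial proportion.

    The interval inverts the binomial tail probabilities: with x
    successes in n trials and alpha = 1 - level, the lower limit solves
    P(X >= x | n, p) = alpha/2 (0 when x = 0) and the upper limit solves
    P(X <= x | n, p) = alpha/2 (1 when x = n).  The solutions are the
    standard beta quantiles Beta(x, n-x+1) and Beta(x+1, n-x).

    Parameters
    ----------
    obs
        Observed successes/trials.
    level
        Two-sided confidence level, typically 0.95 or 0.99.

    Returns
    -------
    ConfidenceInterval
        Exact interval; guaranteed conservative (true coverage at least
        ``level`` for every true proportion).
    """
    if not 0.0 < level < 1.0:
        raise InvalidInputError("confidence level must lie in (0, 1)")
    x, n = obs.successes, obs.trials
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return ConfidenceInterval(level=level, lower=lower, upper=upper)


def midpoint_estimate(target_lower: float) -> float:
    """Point estimate assumed for sizing: midpoint between the metric
    floor and 100%.

    When clinicians fix only the minimum acceptable value of a metric
    (say a 90% floor for PPV), the working point estimate is taken in
    the middle of the admissible band [floor, 100], i.e. (floor+100)/2.
    For small samples this midpoint assumption is optimistic and the
    resulting n should be treated as a lower bound.

    Parameters
    ----------
    target_lower
        Metric floor in percent, in [0, 100].

    Returns
    -------
    float
        Assumed point estimate in percent.
    """
    if not 0.0 <= target_lower <= 100.0:
        raise InvalidInputError("target_lower must lie in [0, 100] percent")
    return (target_lower + 100.0) / 2.0


def round_half_up(value: Fraction | float) -> int:
    """Round to the nearest integer with exact ties going up.

    Expected success counts are rarely integers (0.95 * 150 = 142.5);
    half-up rounding (142.5 -> 143) is the adjustment convention used
    throughout the sizing search.  Exact Fraction arithmetic avoids
    float ties landing on the wrong side.
    """
    f = Fraction(value).limit_denominator(10**12) if not isinstance(
        value, Fraction) else value
    floor, rem = divmod(f.numerator, f.denominator)
    return int(floor + (1 if 2 * rem >= f.denominator else 0))


@dataclass(frozen=True)
class InversionResult:
    """Smallest n meeting a lower-confidence-bound floor, with the
    interval achieved there."""

    n: int
    successes: int
    achieved: ConfidenceInterval


def min_n_for_lower_bound(point_estimate: float, target_lower: float,
                          level: float = 0.95,
                          search_range: tuple[int, int] = (1, DEFAULT_SEARCH_MAX),
                          ) -> InversionResult:
    """Invert the exact interval: smallest n whose lower confidence
    limit reaches the target floor.

    For each candidate n the expected success count is
    round_half_up(point_estimate * n / 100) (clamped to n) and the
    exact Clopper–Pearson interval is computed at that count; the
    smallest n whose lower limit is at least target_lower/100 is
    returned.

    Parameters
    ----------
    point_estimate, target_lower
        In percent; the point estimate must strictly exceed the floor,
        otherwise no finite n can succeed.
    level
        Confidence level of the interval being floored.
    search_range
        Inclusive (lo, hi) range of n to scan.

    Raises
    ------
    InvalidInputError
        If point_estimate <= target_lower.
    NotAchievableError
        If no n in the range meets the floor; the error reports the
        best lower limit found.
    """
    if not 0.0 <= target_lower < 100.0:
        raise InvalidInputError("target_lower must lie in [0, 100) percent")
    if not target_lower < point_estimate <= 100.0:
        raise InvalidInputError(
            "point_estimate must exceed target_lower (a lower confidence "
            "limit is always strictly below the point estimate, so no "
            "finite n can meet the floor otherwise)"
        )
    lo, hi = search_range
    if not 1 <= lo <= hi:
        raise InvalidInputError("search_range must satisfy 1 <= lo <= hi")

    target_p = target_lower / 100.0
    pe = Fraction(point_estimate).limit_denominator(10**9) / 100

    best_n, best_lower = None, -1.0
    # vectorized scan in blocks: beta.ppf over arrays of (x, n)
    block = 4096
    for start in range(lo, hi + 1, block):
        ns = np.arange(start, min(start + block, hi + 1))
        xs = np.array([min(round_half_up(pe * int(n)), int(n)) for n in ns])
        lowers = np.where(
            xs == 0, 0.0,
            stats.beta.ppf((1 - level) / 2, xs, ns - xs + 1),
        )
        ok = lowers >= target_p
        if ok.any():
            i = int(np.argmax(ok))
            n, x = int(ns[i]), int(xs[i])
            return InversionResult(
                n=n, successes=x,
                achieved=clopper_pearson_ci(BinomialObservation(x, n), level),
            )
        i = int(np.argmax(lowers))
        if lowers[i] > best_lower:
            best_lower, best_n = float(lowers[i]), int(ns[i])
    raise NotAchievableError(
        f"no n in [{lo}, {hi}] achieves a {level:.0%} lower confidence "
        f"limit of {target_lower}% at a point estimate of {point_estimate}% "
        f"(best: lower={best_lower:.4f} at n={best_n})",
        best_n=best_n, best_lower=best_lower,
    )
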
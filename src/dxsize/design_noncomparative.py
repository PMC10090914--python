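"""Non-comparative (single new test vs reference test) design.

The study sizes two alternative accuracy metrics — by convention the
predictive values, e.g. a PPV floor and an NPV floor — inverts the
exact confidence interval for each to get a per-metric n, sums the two,
and splits the total between condition-positive ("case") and
condition-negative ("control") patients according to the prevalence of
the condition in the target population.

Which metric is primary (PPV when the task is diagnosis of a common
condition, NPV when it is screening for a rare one) is the user's call
and is only echoed in reports, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError
from .exact_binomial import (
    ConfidenceInterval,
    InversionResult,
    midpoint_estimate,
    min_n_for_lower_bound,
)

__all__ = [
    "NoncomparativeDesign",
    "size_noncomparative",
    "allocate_by_prevalence",
]


@dataclass(frozen=True)
class NoncomparativeDesign:
    """Sized non-comparative design: per-metric n, total and case/control split."""

    target_lower_primary: float
    target_lower_alternative: float
    level: float
    prevalence: float
    n_primary: int
    n_alternative: int
    n_total: int
    n_cases: int
    n_controls: int
    achieved_primary: ConfidenceInterval | None
    achieved_alternative: ConfidenceInterval | None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.n_total == self.n_primary + self.n_alternative
        assert self.n_cases + self.n_controls == self.n_total


def allocate_by_prevalence(total: int, prevalence: float) -> tuple[int, int]:
    """Split a total sample into cases and controls by prevalence.

    cases = round-to-nearest(total * prevalence) with half-up ties,
    controls = total - cases.  A degenerate split (either group empty)
    is allowed but should be surfaced as a warning by callers.
    """
    if total < 1:
        raise InvalidInputError("total must be at least 1")
    if not 0.0 < prevalence < 1.0:
        raise InvalidInputError("prevalence must lie strictly in (0, 1)")
    import math
    cases = int(math.floor(total * prevalence + 0.5))
    cases = min(max(cases, 0), total)
    return cases, total - cases


def size_noncomparative(
    target_lower_primary: float,
    target_lower_alternative: float,
    level: float = 0.95,
    prevalence: float = 0.5,
    override_n: tuple[int, int] | None = None,
) -> NoncomparativeDesign:
    """Size a non-comparative accuracy study from two metric floors.

    Each floor (in percent) is turned into a working point estimate by
    the midpoint heuristic, the exact-interval inversion gives the
    per-metric n, the two are summed, and the total is allocated
    between cases and controls by prevalence.

    Parameters
    ----------
    target_lower_primary, target_lower_alternative
        Lower confidence-limit floors in percent for the primary metric
        and its alternative (e.g. PPV and NPV), each < 100.
    level
        Confidence level for both intervals.
    prevalence
        Prevalence of the target condition in the target population.
    override_n
        Optional (n_primary, n_alternative) pair replacing the minimal
        inversion — used to replicate externally computed per-metric
        sizes.  The achieved intervals are still reported where the
        floors hold at the supplied n.
    """
    warnings: list[str] = []
    if override_n is not None:
        n_primary, n_alternative = override_n
        if n_primary < 1 or n_alternative < 1:
            raise InvalidInputError("override sample sizes must be positive")
        achieved_primary = achieved_alternative = None
    else:
        res_p: InversionResult = min_n_for_lower_bound(
            midpoint_estimate(target_lower_primary), target_lower_primary, level)
        res_a: InversionResult = min_n_for_lower_bound(
            midpoint_estimate(target_lower_alternative), target_lower_alternative, level)
        n_primary, n_alternative = res_p.n, res_a.n
        achieved_primary, achieved_alternative = res_p.achieved, res_a.achieved

    n_total = n_primary + n_alternative
    n_cases, n_controls = allocate_by_prevalence(n_total, prevalence)
    if n_cases == 0 or n_controls == 0:
        warnings.append(
            "prevalence allocation leaves one group empty; the design "
            "cannot estimate both predictive values")

    return NoncomparativeDesign(
        target_lower_primary=target_lower_primary,
        target_lower_alternative=target_lower_alternative,
        level=level,
        prevalence=prevalence,
        n_primary=n_primary,
        n_alternative=n_alternative,
        n_total=n_total,
        n_cases=n_cases,
        n_controls=n_controls,
        achieved_primary=achieved_primary,
        achieved_alternative=achieved_alternative,
        warnings=tuple(warnings),
    )
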
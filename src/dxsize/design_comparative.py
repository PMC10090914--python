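"""Two-proportion sample sizes for superiority and non-inferiority
hypotheses.

Covers two framings with the same arithmetic:

* ``paired-diagnostic`` — a cross-sectional accuracy study where the
  reference, old and new tests are all applied to the same patients;
  the computed n is the single patient sample.
* ``two-arm-rct`` — a randomized trial of a prediction model guiding
  care, with a control and an experimental arm; the computed n is per
  group and the total is twice that.

The sizing formula is the normal-approximation (unpooled-variance)
two-proportion formula without continuity correction.  Superiority uses
a two-sided type I error, non-inferiority a one-sided one:

    superiority:     n = ceil[ (z_{1-a/2} + z_{pow})^2 (p_c q_c + p_n q_n) / (p_n - p_c)^2 ]
    non-inferiority: n = ceil[ (z_{1-a}   + z_{pow})^2 (p_c q_c + p_n q_n) / (p_n - p_c + d)^2 ]

where d > 0 is the non-inferiority margin (largest clinically
acceptable deficit of the new test).  Unequal allocation ratios are
outside this formula's scope and are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "ComparativeSpec",
    "SampleSizeResult",
    "superiority_n",
    "noninferiority_n",
    "inflate_for_dropout",
]

Framing = Literal["paired-diagnostic", "two-arm-rct"]
Hypothesis = Literal["superiority", "noninferiority"]


@dataclass(frozen=True)
class ComparativeSpec:
    """Design parameters for a two-proportion comparison.

    p_control / p_new are success proportions (test accuracies, or
    success rates in the control / experimental arm).  When the design
    is stated in terms of event (disease) frequencies, pass
    ``orientation="event"`` and the complements are taken internally —
    a 20% disease rate is an 80% success rate.
    """

    p_control: float
    p_new: float
    alpha: float = 0.05
    power: float = 0.90
    hypothesis: Hypothesis = "superiority"
    margin: float | None = None
    framing: Framing = "paired-diagnostic"
    orientation: Literal["success", "event"] = "success"

    def __post_init__(self) -> None:
        for name in ("p_control", "p_new", "alpha", "power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidInputError(f"{name} must lie strictly in (0, 1)")
        if self.hypothesis == "noninferiority":
            if self.margin is None or not self.margin > 0.0:
                raise InvalidInputError(
                    "non-inferiority requires a positive margin")
        elif self.margin is not None:
            raise InvalidInputError(
                "margin is only meaningful for the non-inferiority hypothesis")
        if self.framing not in ("paired-diagnostic", "two-arm-rct"):
            raise InvalidInputError(f"unknown framing {self.framing!r}")

    def as_success_rates(self) -> "ComparativeSpec":
        """Normalize to the success-rate orientation."""
        if self.orientation == "success":
            return self
        return replace(self, p_control=1.0 - self.p_control,
                       p_new=1.0 - self.p_new, orientation="success")


@dataclass(frozen=True)
class SampleSizeResult:
    """Computed size with the quantities that produced it."""

    n_per_group: int
    n_total: int
    spec: ComparativeSpec
    z_alpha: float
    z_power: float
    variance_term: float
    n_unrounded: float
    n_inflated: int | None = None
    inflation_pct: float | None = None

    def __post_init__(self) -> None:
        expected_total = (self.n_per_group
                          if self.spec.framing == "paired-diagnostic"
                          else 2 * self.n_per_group)
        assert self.n_total == expected_total
        if self.n_inflated is not None:
            assert self.n_inflated >= self.n_total


def _finish(spec: ComparativeSpec, z_alpha: float, z_power: float,
            effect: float) -> SampleSizeResult:
    s = spec.as_success_rates()
    var = s.p_control * (1 - s.p_control) + s.p_new * (1 - s.p_new)
    n_raw = (z_alpha + z_power) ** 2 * var / effect ** 2
    n = math.ceil(n_raw)
    total = n if spec.framing == "paired-diagnostic" else 2 * n
    return SampleSizeResult(
        n_per_group=n, n_total=total, spec=spec,
        z_alpha=z_alpha, z_power=z_power,
        variance_term=var, n_unrounded=n_raw,
    )


def superiority_n(spec: ComparativeSpec) -> SampleSizeResult:
    """Per-group n to detect a difference between two proportions.

    Two-sided type I error; the null is equality, the alternative the
    stated pair of proportions.  The formula is symmetric in the two
    proportions.
    """
    if spec.hypothesis != "superiority":
        raise InvalidInputError("spec.hypothesis must be 'superiority'")
    s = spec.as_success_rates()
    effect = s.p_new - s.p_control
    if effect == 0.0:
        raise InvalidInputError(
            "superiority is untestable when the proportions are equal: "
            "no finite sample size exists")
    z_alpha = float(stats.norm.ppf(1 - s.alpha / 2))
    z_power = float(stats.norm.ppf(s.power))
    return _finish(spec, z_alpha, z_power, abs(effect))


def noninferiority_n(spec: ComparativeSpec) -> SampleSizeResult:
    """Per-group n to show the new test is at most ``margin`` worse.

    One-sided type I error; the null is that the new proportion falls
    short of the old by the margin or more, the alternative the stated
    pair.  Requires p_new - p_control + margin > 0, otherwise the
    alternative sits on the wrong side of the null boundary and no n
    can succeed.
    """
    if spec.hypothesis != "noninferiority":
        raise InvalidInputError("spec.hypothesis must be 'noninferiority'")
    s = spec.as_success_rates()
    assert s.margin is not None
    effect = s.p_new - s.p_control + s.margin
    if effect <= 0.0:
        raise InvalidInputError(
            "p_new - p_control + margin must be positive: the assumed "
            "truth already violates non-inferiority, so no sample size "
            "can demonstrate it")
    z_alpha = float(stats.norm.ppf(1 - s.alpha))
    z_power = float(stats.norm.ppf(s.power))
    return _finish(spec, z_alpha, z_power, effect)


def inflate_for_dropout(result: SampleSizeResult, pct: float) -> SampleSizeResult:
    """Inflate the total for anticipated dropout/attrition.

    A reserve of 5-10% on top of the computed total is the usual
    planning practice; ``n_inflated = ceil(n_total * (1 + pct/100))``.
    """
    if not 0.0 <= pct <= 50.0:
        raise InvalidInputError("inflation percentage must lie in [0, 50]")
    return replace(result,
                   n_inflated=math.ceil(result.n_total * (1 + pct / 100.0)),
                   inflation_pct=pct)
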
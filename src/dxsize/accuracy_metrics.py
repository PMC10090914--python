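"""Diagnostic accuracy metrics from 2x2 confusion tables and
prevalence adjustment of predictive values.

Sensitivity and specificity are properties of the test alone; the
predictive values PPV and NPV additionally depend on the prevalence of
the target condition, via Bayes' rule:

    PPV = Se*P / [Se*P + (1-Sp)*(1-P)]
    NPV = Sp*(1-P) / [Sp*(1-P) + (1-Se)*P]

so a validation run at one prevalence can be translated to the target
population's prevalence.  Metrics with an empty margin (e.g. PPV when
the test made no positive calls) are undefined and reported as ``None``
rather than silently coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError, UndefinedMetricError

__all__ = [
    "ConfusionTable",
    "AccuracyMetrics",
    "metrics_from_confusion",
    "ppv_adjusted",
    "npv_adjusted",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table of test outcome vs reference-test truth.

    The reference ("gold standard") test defines truth: tp and fn count
    condition-positive patients, fp and tn condition-negative ones.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise InvalidInputError(f"{name} must be a non-negative count")
        if self.total == 0:
            raise InvalidInputError("confusion table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sample_prevalence(self) -> float:
        return (self.tp + self.fn) / self.total


@dataclass(frozen=True)
class AccuracyMetrics:
    """Derived metrics; any metric whose denominator was empty is None."""

    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    accuracy_overall: float
    accuracy_balanced: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(table: ConfusionTable) -> AccuracyMetrics:
    """Compute Se, Sp, PPV, NPV and overall/balanced accuracy from a
    2x2 table.

    se = tp/(tp+fn), sp = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), overall accuracy = (tp+tn)/total, balanced
    accuracy = (se+sp)/2.  Undefined ratios (zero denominator) come
    back as None.
    """
    se = _ratio(table.tp, table.tp + table.fn)
    sp = _ratio(table.tn, table.tn + table.fp)
    return AccuracyMetrics(
        se=se,
        sp=sp,
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        accuracy_overall=(table.tp + table.tn) / table.total,
        accuracy_balanced=(se + sp) / 2 if se is not None and sp is not None else None,
    )


def _check_se_sp_prev(se: float, sp: float, prevalence: float) -> None:
    if not 0.0 <= se <= 1.0 or not 0.0 <= sp <= 1.0:
        raise InvalidInputError("se and sp must lie in [0, 1]")
    if not 0.0 < prevalence < 1.0:
        raise InvalidInputError("prevalence must lie strictly in (0, 1)")


def ppv_adjusted(se: float, sp: float, prevalence: float) -> float:
    """Positive predictive value at a given prevalence.

    PPV = Se*P / [Se*P + (1-Sp)*(1-P)].  Equals the expected
    tp/(tp+fp) in a large population with that prevalence.

    Raises UndefinedMetricError when the test makes no positive calls
    in expectation (se = 0 and sp = 1).
    """
    _check_se_sp_prev(se, sp, prevalence)
    den = se * prevalence + (1.0 - sp) * (1.0 - prevalence)
    if den == 0.0:
        raise UndefinedMetricError(
            "PPV undefined: the test never calls positive (se=0, sp=1)")
    return se * prevalence / den


def npv_adjusted(se: float, sp: float, prevalence: float) -> float:
    """Negative predictive value at a given prevalence.

    NPV = Sp*(1-P) / [Sp*(1-P) + (1-Se)*P].  Equals the expected
    tn/(tn+fn) in a large population with that prevalence.

    Raises UndefinedMetricError when the test makes no negative calls
    in expectation (sp = 0 and se = 1).
    """
    _check_se_sp_prev(se, sp, prevalence)
    den = sp * (1.0 - prevalence) + (1.0 - se) * prevalence
    if den == 0.0:
        raise UndefinedMetricError(
            "NPV undefined: the test never calls negative (sp=0, se=1)")
    return sp * (1.0 - prevalence) / den
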
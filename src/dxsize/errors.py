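"""Exception hierarchy shared by all design modules."""


class DxsizeError(Exception):
    """Base class for all errors raised by dxsize."""


class InvalidInputError(DxsizeError, ValueError):
    """A design parameter is outside its admissible range, or the
    requested design is logically impossible (e.g. a lower confidence
    bound equal to the assumed point estimate)."""


class NotAchievableError(DxsizeError):
    """No sample size within the search range satisfies the requested
    criterion.  Carries the best bound found so the caller can see how
    far short the search fell."""

    def __init__(self, message: str, best_n: int | None = None,
                 best_lower: float | None = None):
        super().__init__(message)
        self.best_n = best_n
        self.best_lower = best_lower


class UndefinedMetricError(DxsizeError, ZeroDivisionError):
    """A 2x2-table metric has a zero denominator and is undefined.

    Metrics with empty margins (e.g. PPV when no positive calls were
    made) are reported as ``None`` in :class:`~dxsize.accuracy_metrics.
    AccuracyMetrics`; this exception is raised only when a scalar
    operation is asked directly for an undefined value.
    """
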
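"""Monte Carlo verification of computed sample sizes.

Every size the formulas produce can be checked by simulation: draw the
two binomial samples at the assumed true proportions, apply the
design's own decision rule, and count rejections.  The decision rule
mirrors the sizing formula — an unpooled-variance z-test (two-sided for
superiority, one-sided shifted by the margin for non-inferiority) — so
the empirical power at the computed n should sit at the nominal power
up to Monte Carlo noise, and the rejection rate under the null at the
nominal type I error.

Reproducibility: every result is fully determined by (seed, reps,
spec, n).  Grid runs derive a per-n sub-seed from the master seed and
the n value itself, so the result at a given n does not depend on the
order or composition of the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design_comparative import ComparativeSpec
from .errors import InvalidInputError

__all__ = ["SimulationResult", "simulate_power", "power_curve"]

# floor on the standard error so zero-variance draws (all successes or
# all failures in both arms) give a finite, deterministic statistic
_SE_EPS = 1e-12


@dataclass(frozen=True)
class SimulationResult:
    reps: int
    seed: int
    n_per_group: int
    rejections: int
    empirical_power: float
    mc_se: float

    def __post_init__(self) -> None:
        assert self.rejections <= self.reps
        assert math.isclose(self.empirical_power, self.rejections / self.reps)


def _decision_rule(spec: ComparativeSpec, xc: np.ndarray, xn: np.ndarray,
                   n: int) -> np.ndarray:
    """Vector of reject/accept decisions for simulated count pairs."""
    pc_hat = xc / n
    pn_hat = xn / n
    se = np.sqrt(pc_hat * (1 - pc_hat) / n + pn_hat * (1 - pn_hat) / n)
    se = np.maximum(se, _SE_EPS)
    if spec.hypothesis == "superiority":
        z = (pn_hat - pc_hat) / se
        return np.abs(z) > stats.norm.ppf(1 - spec.alpha / 2)
    z = (pn_hat - pc_hat + spec.margin) / se
    return z > stats.norm.ppf(1 - spec.alpha)


def simulate_power(spec: ComparativeSpec, n_per_group: int,
                   true_p_control: float, true_p_new: float,
                   reps: int = 100_000, seed: int = 0) -> SimulationResult:
    """Empirical rejection rate of the design's z-test at a given n.

    Set the true proportions to the design's alternative to estimate
    power, or to a null configuration (equal proportions for
    superiority; new = control - margin for non-inferiority) to
    estimate the realized type I error.

    Parameters
    ----------
    spec
        The comparative design whose decision rule is simulated.
    n_per_group
        Patients per group in each simulated trial.
    true_p_control, true_p_new
        True success probabilities used for the draws (in the
        success-rate orientation).
    reps
        Number of simulated trials; at least 1000.
    seed
        Master seed; identical (seed, reps, spec, n) give identical
        output.
    """
    if reps < 1000:
        raise InvalidInputError("reps must be at least 1000 for a usable estimate")
    if n_per_group < 2:
        raise InvalidInputError("n_per_group must be at least 2")
    for p in (true_p_control, true_p_new):
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError("true proportions must lie in [0, 1]")
    s = spec.as_success_rates()
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_per_group]))
    xc = rng.binomial(n_per_group, true_p_control, size=reps)
    xn = rng.binomial(n_per_group, true_p_new, size=reps)
    rejections = int(_decision_rule(s, xc, xn, n_per_group).sum())
    emp = rejections / reps
    return SimulationResult(
        reps=reps, seed=seed, n_per_group=n_per_group,
        rejections=rejections, empirical_power=emp,
        mc_se=math.sqrt(emp * (1 - emp) / reps),
    )


def power_curve(spec: ComparativeSpec, n_grid: list[int],
                true_p_control: float, true_p_new: float,
                reps: int = 20_000, seed: int = 0
                ) -> list[tuple[int, float]]:
    """Empirical power over an ascending grid of per-group sizes.

    Each grid point uses its own sub-seed derived from (seed, n), so
    the curve is reproducible point-by-point regardless of the grid.
    """
    if not n_grid:
        raise InvalidInputError("n_grid must be non-empty")
    if list(n_grid) != sorted(n_grid):
        raise InvalidInputError("n_grid must be ascending")
    return [
        (n, simulate_power(spec, n, true_p_control, true_p_new,
                           reps=reps, seed=seed).empirical_power)
        for n in n_grid
    ]
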
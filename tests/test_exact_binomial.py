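"""Exact Clopper–Pearson intervals and the sample-size inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from dxsize.errors import InvalidInputError, NotAchievableError
from dxsize.exact_binomial import (
    BinomialObservation,
    clopper_pearson_ci,
    midpoint_estimate,
    min_n_for_lower_bound,
    round_half_up,
)


def cp_bisect_oracle(x: int, n: int, level: float) -> tuple[float, float]:
    """Independent interval oracle: bisection on the exact binomial
    tail sums (never touches the beta-quantile route the
    implementation uses)."""
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else optimize.brentq(
        lambda p: (1 - stats.binom.cdf(x - 1, n, p)) - alpha / 2,
        1e-15, 1 - 1e-15, xtol=1e-14)
    upper = 1.0 if x == n else optimize.brentq(
        lambda p: stats.binom.cdf(x, n, p) - alpha / 2,
        1e-15, 1 - 1e-15, xtol=1e-14)
    return lower, upper


class TestClopperPearsonCI:
    def test_published_ppv_interval(self):
        """143/150 at 95% gives (90.6%, 98.1%) to one decimal."""
        iv = clopper_pearson_ci(BinomialObservation(143, 150), 0.95)
        assert round(100 * iv.lower, 1) == 90.6
        assert round(100 * iv.upper, 1) == 98.1

    @pytest.mark.parametrize("x,n,side,expected", [
        (0, 20, "lower", 0.0),
        (20, 20, "upper", 1.0),
    ])
    def test_boundary_counts_pin_bounds(self, x, n, side, expected):
        iv = clopper_pearson_ci(BinomialObservation(x, n), 0.95)
        assert getattr(iv, side) == expected

    def test_small_sample_matches_frozen_bisection_oracle(self):
        """2/10 bounds frozen from tail-sum bisection before the
        beta-quantile implementation existed."""
        iv = clopper_pearson_ci(BinomialObservation(2, 10), 0.95)
        assert iv.lower == pytest.approx(0.0252107263, abs=1e-9)
        assert iv.upper == pytest.approx(0.5560954623, abs=1e-9)

    def test_agrees_with_bisection_oracle_all_small_n(self):
        """Beta-quantile bounds match exact tail-sum bisection to 1e-6
        for every (x, n) with n <= 30."""
        for n in range(1, 31):
            for x in range(n + 1):
                iv = clopper_pearson_ci(BinomialObservation(x, n), 0.95)
                lo, hi = cp_bisect_oracle(x, n, 0.95)
                assert iv.lower == pytest.approx(lo, abs=1e-6), (x, n)
                assert iv.upper == pytest.approx(hi, abs=1e-6), (x, n)

    @given(n=st.integers(1, 500), frac=st.floats(0, 1),
           level=st.sampled_from([0.90, 0.95, 0.99]))
    @settings(max_examples=200, deadline=None)
    def test_matches_statsmodels_and_brackets_estimate(self, n, frac, level):
        """Cross-check against statsmodels' exact interval; interior
        counts are strictly bracketed by the interval."""
        x = int(round(frac * n))
        iv = clopper_pearson_ci(BinomialObservation(x, n), level)
        sm_lo, sm_hi = proportion_confint(x, n, alpha=1 - level, method="beta")
        assert iv.lower == pytest.approx(float(np.nan_to_num(sm_lo)), abs=1e-10)
        assert iv.upper == pytest.approx(float(np.nan_to_num(sm_hi, nan=1.0)), abs=1e-10)
        if 0 < x < n:
            assert iv.lower < x / n < iv.upper

    def test_exhaustive_coverage_is_conservative(self):
        """For every n <= 25 the 95% interval covers each true p on a
        0.01 grid with probability >= 0.95 (exact enumeration)."""
        ps = np.arange(0.01, 1.0, 0.01)
        for n in range(1, 26):
            xs = np.arange(n + 1)
            lowers = np.array([clopper_pearson_ci(
                BinomialObservation(int(x), n)).lower for x in xs])
            uppers = np.array([clopper_pearson_ci(
                BinomialObservation(int(x), n)).upper for x in xs])
            pmf = stats.binom.pmf(xs[:, None], n, ps[None, :])
            covered = (lowers[:, None] <= ps[None, :]) & (ps[None, :] <= uppers[:, None])
            coverage = (pmf * covered).sum(axis=0)
            assert (coverage >= 0.95 - 1e-12).all(), n

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_width_shrinks_with_scaled_sample(self, k):
        """Same success fraction, k-fold sample: interval narrows."""
        base = clopper_pearson_ci(BinomialObservation(7, 10))
        scaled = clopper_pearson_ci(BinomialObservation(7 * k, 10 * k))
        assert scaled.width < base.width

    def test_zero_trials_rejected(self):
        with pytest.raises(InvalidInputError):
            BinomialObservation(0, 0)


class TestMidpointEstimate:
    @pytest.mark.parametrize("floor,expected", [(90, 95), (80, 90), (100, 100)])
    def test_midpoint_of_floor_and_100(self, floor, expected):
        assert midpoint_estimate(floor) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            midpoint_estimate(101)


class TestRoundHalfUp:
    @pytest.mark.parametrize("v,expected", [
        (142.5, 143), (21.3, 21), (127.8, 128), (56.7, 57), (2.5, 3), (-0.0, 0),
    ])
    def test_ties_go_up(self, v, expected):
        assert round_half_up(v) == expected


class TestMinNForLowerBound:
    @pytest.mark.parametrize("pe,floor,published_n", [(95, 90, 150), (90, 80, 63)])
    def test_minimum_matches_exhaustive_scan_and_published_n_qualifies(
            self, pe, floor, published_n):
        """The returned n equals an exhaustive scan's minimum, and the
        conventional published sizes (150 for a 90% PPV floor, 63 for
        an 80% NPV floor) also satisfy the bound — they are valid but
        not minimal."""
        res = min_n_for_lower_bound(pe, floor, 0.95)
        # independent exhaustive scan against the bisection oracle
        scan_min = None
        for n in range(1, 501):
            x = min(round_half_up(pe * n / 100), n)
            lo = 0.0 if x == 0 else cp_bisect_oracle(x, n, 0.95)[0]
            if lo >= floor / 100:
                scan_min = n
                break
        assert res.n == scan_min
        assert res.achieved.lower >= floor / 100
        x_pub = min(round_half_up(pe * published_n / 100), published_n)
        assert cp_bisect_oracle(x_pub, published_n, 0.95)[0] >= floor / 100

    def test_floor_equal_to_estimate_is_impossible(self):
        with pytest.raises(InvalidInputError):
            min_n_for_lower_bound(90, 90, 0.95)

    def test_exhausted_search_range_raises_with_best_found(self):
        with pytest.raises(NotAchievableError) as exc:
            min_n_for_lower_bound(90.1, 90, 0.95, search_range=(1, 200))
        assert exc.value.best_lower is not None
        assert exc.value.best_lower < 0.90

    @pytest.mark.parametrize("pe_pairs", [((95, 90), (96, 90)), ((92, 80), (95, 80))])
    def test_larger_gap_needs_no_more_patients(self, pe_pairs):
        """n is non-increasing in the gap between estimate and floor."""
        (pe1, fl1), (pe2, fl2) = pe_pairs
        assert min_n_for_lower_bound(pe2, fl2).n <= min_n_for_lower_bound(pe1, fl1).n

    def test_higher_confidence_needs_no_fewer_patients(self):
        assert (min_n_for_lower_bound(95, 90, 0.99).n
                >= min_n_for_lower_bound(95, 90, 0.95).n)
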
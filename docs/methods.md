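# Methods

## Scope and model

`dxsize` sizes prospective clinical trials whose primary outcome is a
binary classification: a diagnostic or screening test (often a
machine-learning model) judged against a reference test assumed to be
error-free, or a two-arm randomized trial of a model-guided care
strategy with a binary success endpoint. Three designs are covered:
non-comparative accuracy studies sized by confidence-interval
inversion, and superiority / non-inferiority comparisons of two
proportions. Time-to-event endpoints, equivalence designs, AUROC-based
sizing, and unequal randomization ratios are out of scope.

## Non-comparative design: interval inversion

The accuracy metrics Se, Sp, PPV and NPV are binomial proportions, so
the design reduces to: given a clinician-set floor L (in percent) on
the lower limit of the two-sided exact Clopper–Pearson interval, find
the smallest n at which the floor is met.

* **Point estimate.** Only the floor is elicited; the working point
  estimate is the midpoint (L+100)/2 of the admissible band. This is
  deliberately simple and optimistic for small samples; if a pilot
  estimate exists it can be supplied directly to
  `min_n_for_lower_bound`.
* **Expected successes.** p̂·n is rarely an integer; the count is
  rounded half-up (0.95·150 = 142.5 → 143), computed in exact rational
  arithmetic so ties never depend on float representation. This
  convention is pinned by the requirement that the achieved interval
  at (143, 150) is (90.6%, 98.1%) to one decimal.
* **Interval computation.** The exact bounds are the beta quantiles
  Beta(α/2; x, n−x+1) and Beta(1−α/2; x+1, n−x), evaluated with
  `scipy.stats.beta.ppf` (x = 0 and x = n pin the bounds to 0 and 1).
  The test suite cross-checks every (x, n) with n ≤ 30 against an
  independent bisection on the binomial tail sums (tolerance 1e−6)
  and against `statsmodels.stats.proportion.proportion_confint
  (method="beta")`, and verifies conservative coverage exhaustively
  for n ≤ 25 on a 0.01 grid of true proportions.
* **Search.** n is scanned upward (vectorized in blocks) over a
  bounded range, default 1..100 000; exhaustion raises a loud
  not-achievable error carrying the best lower limit found, since a
  floor close to the point estimate makes n explode. A floor at or
  above the point estimate is rejected outright — the lower limit of a
  two-sided interval is always strictly below the estimate.
* **Minimal vs conventional sizes.** The strictly minimal sizes for
  the reference floors (point 95/floor 90 and point 90/floor 80 at
  95% confidence) are 127 and 55. The sizes in common circulation for
  these floors, 150 and 63, are larger but also satisfy the criterion
  (calculator probing rather than exact minimization, evidently).
  Both behaviors are first-class: the default policy returns the
  strict minimum; `override_n` reproduces externally supplied
  per-metric sizes. The quoted NPV interval "(80.5%; 95.9%)" at n = 63
  matches no exact interval at any nearby integer count (57/63 gives
  (80.4%, 96.4%)); the suite therefore asserts only that the 80% floor
  holds at n = 63, and records the digit mismatch as a known
  discrepancy of that quoted interval.
* **Allocation.** The summed total is split into cases and controls by
  prevalence with round-to-nearest (half-up) — the only convention
  consistent with both reference allocations (213·0.6 = 127.8 → 128;
  213·0.1 = 21.3 → 21). A split that empties either group attaches a
  warning rather than failing. Which metric is "primary" (PPV for
  diagnosis of a common condition, NPV for screening a rare one) is
  the user's declaration, echoed in reports, never inferred.

## Comparative designs: two-proportion formulas

The normal-approximation formula with unpooled variance and no
continuity correction is used, with full-precision normal quantiles
(z₀.₉₇₅ = 1.959964…, z₀.₉₅ = 1.644854…, z₀.₉₀ = 1.281552…) and
ceiling rounding:

* superiority (two-sided α): n = ⌈(z₁₋α/₂+z_pow)²(p_c q_c+p_n q_n)/(p_n−p_c)²⌉
* non-inferiority (one-sided α, margin d > 0):
  n = ⌈(z₁₋α+z_pow)²(p_c q_c+p_n q_n)/(p_n−p_c+d)²⌉

This exact combination — two-sided α for superiority, one-sided for
non-inferiority, unpooled variance, no correction — is the one that
reproduces all five reference sizes (263; 1097; 560; 538; 1097) and is
the basis the Monte Carlo layer verifies. A continuity-corrected
variant does not reproduce 263 and is not offered.

Two framings share the arithmetic: `paired-diagnostic` (reference, old
and new test all applied to one patient sample; total = n) and
`two-arm-rct` (total = 2n). The unpaired formula is used in both — a
paired correction for the cross-sectional framing would need a
correlation parameter the elicitation does not include, and the
computed n is conservative relative to a positively correlated paired
analysis. Designs stated as event (disease) frequencies are accepted
with `orientation="event"` and complemented internally (a 20% disease
rate is an 80% success rate).

Non-inferiority requires p_new − p_control + d > 0; otherwise the
assumed truth already violates non-inferiority and no n succeeds.
Equal proportions make superiority untestable. Both are rejected as
invalid input, not returned as huge n. Dropout inflation is
n_inflated = ⌈n_total·(1+pct/100)⌉, with 5–10% the usual planning
reserve; percentages above 50 are rejected as implausible.

Whether non-inferiority always needs more patients than superiority
depends on the margin relative to the assumed effect; the suite checks
the inequality only for the reference design pairs (1097 > 263), not
as a theorem.

## Monte Carlo verification

`power_sim` re-derives each size empirically: draw `reps` pairs of
binomial samples at the true proportions and apply the design's own
decision rule — the unpooled-variance z-test, two-sided for
superiority, shifted by the margin and one-sided for non-inferiority.
Using the same variance as the sizing formula is deliberate: a
different rule (e.g. Fisher's exact test) would confound formula error
with rule mismatch.

* Reproducibility: the generator is seeded with
  `SeedSequence([seed, n])`, so a result at a given n is independent
  of the grid it was computed in.
* Degenerate draws (zero variance in both arms) are handled by
  flooring the standard error at 1e−12: a zero observed difference
  gives z = 0 (never a rejection for superiority; a rejection for
  non-inferiority, where the margin alone makes the shifted statistic
  positive). Deterministic, never a crash.
* Calibration: at each computed reference size, empirical power at
  100 000 replications lies within 0.02 of the nominal 0.90, and the
  rejection rate at the null boundary within 0.01 of α = 0.05 (checked
  in the suite; Monte Carlo SE at 100 000 reps is ≈ 0.001–0.0015, so
  these bands also absorb the small asymptotic-vs-exact gap).

There is no synthetic-data generator in the usual sense: the designs
take parameters, not datasets, and the simulation layer *is* the
data-generating model (independent binomial arms at the stated true
proportions). What passing simulations do not show: robustness to
non-representative sampling, reference-test error, or correlation
between tests read on the same patients.

## Interface conventions

Percentages at the CLI (the clinical idiom: `--p-control 80
--alpha 5`), proportions in config files and throughout the internal
math; `percent_convention: true` switches a config file to percent.
Metric floors are always percent. Reports render to text and JSON with
identical numbers (floats printed at 6 significant digits via the same
format call), and JSON reports round-trip losslessly. Undefined 2×2
metrics (empty margins) are `None`/`undefined`, never silently 0 or 1.
Exit codes: 0 success, 2 validation error, 3 not-achievable design.

## Numerical notes and limitations

* Beta quantiles from scipy are accurate to well below the 1e−6
  cross-check tolerance; reported bounds are stable to 3 decimals.
* The midpoint point-estimate heuristic is optimistic for small n;
  the returned non-comparative sizes are lower bounds in that sense.
* The normal-approximation comparative formula can be anticonservative
  for proportions near 0 or 1 or very small n; the Monte Carlo layer
  exists precisely to check realized power/type I error at the
  returned n before a protocol is finalized.
* Confidence intervals on prevalence-adjusted PPV/NPV are not
  provided; sizing operates on the unadjusted proportion scale.
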
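# dxsize

Sample-size determination for clinical trials of diagnostic/screening
tests and binary-outcome predictive decision-support models.

When a new diagnostic test (often a machine-learning model) is taken to
a prospective trial, the protocol must state how many patients will be
enrolled and why. `dxsize` implements the standard calculations for the
three designs that cover most such trials, and lets every computed size
be verified by Monte Carlo simulation:

1. **Non-comparative accuracy study** (new test vs a reference "gold
   standard"). Clinicians fix floors on the lower 95% confidence limit
   of the predictive values — e.g. PPV ≥ 90%, NPV ≥ 80%. Taking the
   midpoint of the admissible band as the working point estimate
   ((floor+100)/2), the exact Clopper–Pearson interval

   lower: solves P(X ≥ x | n, p) = α/2,  upper: solves P(X ≤ x | n, p) = α/2

   is inverted to the smallest *n* whose lower limit reaches the floor.
   The per-metric sizes are summed and the total split into
   condition-positive and condition-negative patients by the prevalence
   of the condition in the target population.

2. **Comparative study, superiority** (new vs old test, or a two-arm
   RCT of a model-guided strategy). Normal-approximation two-proportion
   formula, two-sided α, no continuity correction:

   n = ⌈(z₁₋α/₂ + z_pow)² · (p_c q_c + p_n q_n) / (p_n − p_c)²⌉

3. **Comparative study, non-inferiority** with margin d > 0, one-sided α:

   n = ⌈(z₁₋α + z_pow)² · (p_c q_c + p_n q_n) / (p_n − p_c + d)²⌉

A 2×2 confusion-table module computes Se, Sp, PPV, NPV and translates
predictive values between prevalences via Bayes' rule
(PPV = Se·P / [Se·P + (1−Sp)(1−P)], NPV = Sp(1−P) / [Sp(1−P) + (1−Se)P]),
and the `power_sim` module re-derives every comparative size
empirically with a seeded unpooled-variance z-test simulation.

## Worked example

A new test with assumed point-estimate PPV 95% must demonstrate a 95%
lower confidence limit of at least 90%; NPV floor 80%. Using the
conventional per-metric sizes 150 and 63 and a target-population
prevalence of 60%:

```
$ dxsize diag-noncomp --ppv-lower 90 --npv-lower 80 --prevalence 0.6 --override-n 150,63
dxsize design report — noncomparative

Inputs:
  level: 0.95
  override_n: [150, 63]
  prevalence: 0.6
  target_lower_alternative: 80
  target_lower_primary: 90
Results:
  achieved_ci_alternative: None
  achieved_ci_primary: None
  n_alternative: 63
  n_cases: 128
  n_controls: 85
  n_primary: 150
  n_total: 213
```

213 patients in total: 128 with the condition and 85 without, matching
the 60% prevalence. At n = 150 the exact interval behind the PPV floor
is

```
$ dxsize ci --successes 143 --trials 150
point estimate: 95.3%
95% CI: (90.6%; 98.1%)
```

— the lower limit 90.6% clears the 90% floor. (Without `--override-n`
the tool returns the strictly minimal sizes, 127 and 55, which also
clear the floors; see `docs/methods.md`.)

A two-arm RCT showing a model-guided strategy is non-inferior to usual
care (success rate 80% in both arms, margin 5%, one-sided α = 5%,
power 90%):

```
$ dxsize rct-noninf --p-control 80 --p-new 80 --margin 5
...
  n_per_group: 1097
  n_total: 2194
```

and the size can be checked by simulation (`dxsize power-sim --design
saved.json --reps 100000 --seed 17` reports an empirical power of
about 0.90 at n = 1097).

Comparative flags are given in percent; config files (`dxsize run
--config design.yaml`) use proportions unless they set
`percent_convention: true`. Exit codes: 0 success, 2 invalid input,
3 design not achievable.

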
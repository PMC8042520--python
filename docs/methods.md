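# Methods

## Model structure and assumptions

The engine is a deterministic expected-value cohort model. Each model year
an independent cohort of `annual_baseline_screeners` people — everyone who
would have completed CRC screening that year under pre-pandemic conditions —
is partitioned by the scenario's uptake schedule into colonoscopy users, FIT
users, and the unscreened. Annual cohorts are disjoint: nobody screens
twice, and undiagnosed cancers do not carry over to the next year's cohort.
That mirrors the short-horizon budget-impact framing the model serves; it
understates cumulative detection among people who would re-attempt
screening, and it makes all outcomes additive across years.

Within a cohort, prevalent cancers (prevalence π, one shared value for all
three arms) follow one of three detection paths:

1. **Screening colonoscopy** detects with probability `sens_colo` (0.95).
2. **FIT** detects with probability `sens_FIT × adherence` (0.79 × 0.65 =
   0.5135): a cancer must both trigger a positive test and be followed by a
   completed diagnostic colonoscopy. The 7% marginal positivity rate does
   *not* enter case detection — it drives the reported
   diagnostic-colonoscopy demand (`screened_FIT × 0.07 × 0.65`) and the
   microsimulator's false-positive draw. The sensitivity-times-adherence
   path is used because every one of its parameters is published, whereas a
   positivity × PPV path would require an unpublished PPV.
3. **Clinical presentation**: every cancer not screen-detected — colonoscopy
   false negatives, FIT false negatives, FIT true positives lost to
   follow-up, and all cancers among the unscreened — joins one undiagnosed
   pool, of which a fraction `q` presents symptomatically within the
   horizon. `q` is applied uniformly to all components of the pool; the
   source evidence does not distinguish their presentation rates.

Detected cases draw a stage from the detection route's distribution
(screening colonoscopy 34/36/19/11, FIT 36.7/34.7/21.7/6.9, clinical
18/34/23/25 for stages I–IV). Stage shift is captured entirely by these
three static distributions; there is no explicit dwell-time or progression
model, and no mortality, survival or cost outputs.

## Calibration of the symptomatic fraction

The fraction `q` of undiagnosed cancers presenting clinically is not
published; only the baseline outcome it generates is (576 symptom-detected
cases over 3 years). Because every outcome is linear in `q`, calibration is
closed-form: `q = 576 / pool(baseline)` = 576 / 4,333.2 ≈ 0.1329. The
calibrated `q` is reused unchanged across scenarios, which treats
symptomatic presentation as a property of undiagnosed disease, not of the
scenario. A user-supplied `q` can replace the calibrated one via config.

## Parameters

| parameter | default | 95% CI | units |
|---|---|---|---|
| colonoscopy sensitivity | 0.95 | 0.90–1.00 | probability |
| CRC prevalence | 0.008 | 0.007–0.009 | proportion of cohort |
| FIT sensitivity | 0.79 | 0.69–0.85 | probability |
| FIT positivity | 0.07 | 0.063–0.077 | marginal probability |
| diagnostic adherence | 0.65 | 0.52–0.78 | probability |
| annual cohort | 1,563,556 | — | persons/year |
| horizon | 3 | — | years |
| baseline mix | 0.85 / 0.15 | — | colonoscopy / FIT |

The prevalence default follows the published input table (0.8%); the
accompanying text's 0.08% reading is configurable but produces case counts
an order of magnitude below the published results table, so 0.8% is treated
as the intended value.

## Uptake schedules

The five published schedules are canonical and stored verbatim as
whole-percent cells. Because some printed rows over- or under-sum by one
point, yearly sums are accepted in [0.99, 1.01] and the engine recomputes
the unscreened remainder as `1 − p_colo − p_fit`, preserving the printed
modality columns. Year boundaries are calendar (months 1–12, 13–24, 25–36).

`schedule_from_profile` derives schedules generatively from a monthly
volume-multiplier profile (e.g. 3 months normal, 3 months shutdown, 9
months at 50%, 21 at 75%), duration-weighting each year's months;
`apply_fit_expansion` moves a fixed fraction (default 22.5%, the median
mailed-outreach FIT completion of a large integrated system) of each year's
unscreened pool to FIT. These utilities reproduce the published colonoscopy
columns exactly after rounding, but no single profile-plus-rule pair
reproduces every published FIT cell (the published FIT column in the
no-expansion scenarios stays flat at 8% while colonoscopy recovers, and the
expansion cells 17/22/27/21% are not derivable from the stated 22.5% rule),
so published-scenario runs always use the canonical cells.

## Known departures from the published comparison table

Two kinds of published numbers are not exactly recoverable from the
published inputs, and this package reports what the model actually yields
rather than adjusting toward the printed values:

- **Screening deltas.** The whole-percent schedule cells give a
  scenario-3-vs-1 gain of 562,880 and a scenario-4-vs-2 gain of 641,058
  screenings, 2–4% below the published 588,845 and 655,825; the original
  analysis evidently used unrounded uptake fractions.
- **Case deltas through the symptomatic pathway.** With the calibrated
  `q ≈ 0.133`, every extra FIT screening also removes `q × π × 0.5135`
  expected symptom-detected cases from the comparator, so the
  scenario-4-vs-2 diagnosis gain is `ΔFIT × π × 0.5135 × (1 − q)` ≈ 2,283
  with an early-stage share of 74.4%. The published 2,715 (71.6% early)
  implies a symptom-detected difference of only −29 cases between the two
  scenarios, which no constant symptomatic fraction consistent with the
  published baseline count can produce; the published per-scenario
  screen/symptom splits are likewise internally inconsistent (the
  scenario-3 and scenario-4 split cells appear transposed). The
  per-scenario totals, by contrast, agree with the model within 0.4–3%.

## Microsimulation oracle

The microsimulator realizes the identical assumptions at person level:
modality ~ categorical(p_colo, p_fit, p_none); cancer ~ Bernoulli(π);
colonoscopy detection ~ Bernoulli(sens_colo); FIT positivity ~
Bernoulli(sens_FIT) given cancer and Bernoulli((0.07 − π·sens_FIT)/(1 − π))
given no cancer, so the marginal positivity stays at 7%; follow-up ~
Bernoulli(adherence); symptomatic presentation ~ Bernoulli(q); stage ~
categorical by route. Counts scale by `B / n_persons_per_year` to cohort
scale. Replicate `r` uses the independent stream `default_rng(seed + r)`,
so individual replicates are reproducible; simulation is vectorized over
persons, which leaves the sampling distribution unchanged. Defaults
(200,000 persons/year, 50 replicates) put Monte-Carlo standard errors near
60–70 persons on case counts and run in about a second per scenario.

Because the simulator shares the engine's assumptions, agreement between
the two validates the arithmetic, not the model's realism: neither captures
repeat screening, within-year timing, age structure, or correlation between
screening behaviour and cancer risk. The exported person table is synthetic
data generated from these assumptions.

## Sensitivity analysis

The published 95% CIs are propagated even though the original analysis
reports none; this module is an extension. One-way sweeps set each CI-bearing
parameter to its bounds (tornado ordering: descending swing, ties
alphabetical; `q` held at its base calibrated value unless re-calibration
is requested). The probabilistic analysis draws each proportion from a beta
distribution whose 2.5th/97.5th percentiles are fitted to the CI by least
squares on (log a, log b) — beta rather than normal because every varied
input is a probability, making truncation unnecessary. The colonoscopy
sensitivity CI's upper bound of 1.0 is clipped to 1 − 1e−9, since a proper
beta cannot place its 97.5th percentile exactly at 1; the fitted 2.5th
percentile remains within 5e−3 of 0.90. Stage proportions carry no
published CIs and are held fixed (their stored ranges are degenerate).

## Numerical conventions

- All intermediate counts are real-valued expectations; published-style
  tables round half away from zero at render time; comparisons are computed
  unrounded, then rounded.
- Percent differences with a zero reference are reported as NA, never ±inf.
- Stage-proportion sums are accepted within 0.005 of 1 (the published
  distributions sum to exactly 1 at printed precision).
- Unscreened remainders below 1e−12 are treated as exactly zero to keep the
  baseline's empty unscreened arm free of floating-point dust.

## Test and validation problem sizes

Unit tests run the engine at full cohort scale (it is closed-form and
instant). The oracle-equivalence suite uses 200,000 simulated persons per
year × 50 replicates × 20 base seeds spaced 1,000 apart (so replicate
streams never overlap between bases), requiring every outcome within 3
Monte-Carlo SE for at least 19 of 20 bases; randomized invariant suites use
200 parameter/schedule draws.
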
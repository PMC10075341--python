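# Methods

This note records the models implemented in `ursamark`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
generator does and does not emulate.

## Event model and independence

A camera trigger (one short video) is a *detection*; a *visit event* is a
maximal cluster of same-site detections in which each detection follows the
previous one by no more than the independence window. The window defaults
to 30 minutes — the common camera-trap convention — and is configurable;
the gap rule chains, so a long visit that re-triggers the camera every few
minutes remains one event. Filtering is idempotent: events produced by the
rule are themselves separated by more than the window.

Sex/age classes are stored at fine resolution (nine labels, including
`female_with_cubs` and the unknown-adult/subadult labels) with a fixed map
onto five reporting classes: females with cubs report as adult females,
subadults of either or unknown sex pool as `subadult`, adults of unknown
sex fall into `unknown`. Timestamps are stored and reported in UTC; site
UTC offsets exist only as metadata, since all solar arithmetic is done
directly in UTC.

### Tabulation conventions

- Printed percentages are rounded half-up to one decimal. Because each of
  the five class rows rounds independently, a class × category column sums
  to 100 within ±0.05 per row (±0.25 for five rows), not ±0.1; published
  tables of this kind show the same artifact (columns summing to 100.1).
- Duration summaries zero-fill: an event that lacks a behavior contributes
  0 s to that behavior, which is why minima are 0 whenever any event lacks
  it. SD is the sample standard deviation, defined as 0 for a single
  event.
- Behavior categories for the class table: investigation-only,
  investigation-and-marking, marking-only, visual marking, pedal marking.
  The last two are not exclusive of the first three.

## Behavioral sequences

Sequences run from the first coded behavior of a visit to departure. Two
standard views ship as presets: a 3-state *diagram* view (dorsal+facial →
`rubbing`, the three debarking codes → `debarking`, investigation dropped
because it occurs around essentially every transition) and a 5-state
*full-chain* view (all behaviors, debarking codes merged). Runs of the
same state collapse to one state — a continued behavior is not a
self-transition — and virtual START/END states bracket each visit, so entry
and exit behaviors are ordinary rows/columns of the matrix.

Transition probabilities are row-normalized counts pooled per transition
across sequences (not per sequence). Pruning at the default threshold 0.1
removes edges with probability *strictly below* the threshold from diagram
export only; probabilities are deliberately not renormalized, because
pruning is a display decision, not a model change.

## Solar computations

Sunrise and sunset come from the NOAA solar-position equations (geometric
mean longitude/anomaly, equation of center, apparent longitude, corrected
obliquity, equation of time) at the official zenith of 90.833°, evaluated
at the site's approximate solar noon. Agreement with almanac values is
within ~1–2 minutes at mid-latitudes; polar day/night raises an explicit
error. At the study latitude (43.1° N) the computed daylight is ≈ 9 h 22
in mid-January and ≈ 15 h 21 in mid-June, a ≈ 6-h seasonal swing.

Four diel periods tile the 24-h day with half-open intervals:
sunrise = [sunrise−1 h, sunrise+1 h), day = [sunrise+1 h, sunset−1 h),
sunset = [sunset−1 h, sunset+1 h), night = the rest. Night is attributed
to the calendar date of its evening portion.

The sun-relative time transform is a five-anchor piecewise-linear map:
solar midnight → −1/+1, sunrise → −0.5, solar noon (midpoint of sunrise
and sunset) → 0, sunset → +0.5. It is continuous, strictly increasing over
the diel cycle, spans exactly [−1, +1], considers both sunrise and sunset,
and is invertible (the generator uses the inverse to place event times).
Other constructions satisfying the same verbal description exist; this one
was chosen for invertibility and for keeping the two 2-h anchor periods at
fixed widths on the clock.

Survey effort counts any calendar day with at least one hour of deployment
as a full camera-trap day (only an annual total was ever published, so a
finer convention cannot be checked). Monthly activity is
RIC = 1000 × independent captures / camera-trap days. "Julian date" is
day-of-year (1 = 1 January), the ecological usage, not astronomical JD.

## Inference

- **χ² goodness of fit with exposure.** Expected counts are proportional
  to an exposure vector: trap days per month for the monthly test; summed
  per-day period durations over all deployed site-days for the period
  test. χ² = Σ(O−E)²/E on bins−1 df. Expected cells below 1 produce a
  warning, not a failure.
- **Exact binomial post hocs.** Bin i is tested as k_i successes in
  N = Σ observed trials at p₀ = exposure share. Two-sidedness doubles the
  smaller tail and caps at 1 — monotone in |k − Np₀|, unlike
  minimum-likelihood two-siding. Bonferroni m = number of bins tested (12
  months, 4 periods).
- **Debarking GLM.** Binomial family, logit link, fitted by IRLS
  (statsmodels; max 50 iterations, tolerance 1e−8). Covariates are left in
  raw units (days; sun time in [−1, 1]). Wald CIs use estimate ± 1.96·SE.
  Complete separation and non-convergence raise explicit errors. Candidate
  term sets (intercept; +julian; +sun time; both; both + interaction) are
  compared by AICc; models within 2 of the minimum are flagged as
  competing.
- **Durations.** One-way ANOVA across behaviors on per-event zero-filled
  durations of events with timed natural visual marks, followed by Tukey
  HSD (studentized-range p-values; the reported t is the pairwise
  difference over its pooled-variance standard error).

## Synthetic generator: what it emulates

Defaults state one study-like year: 13 sites near 43° N deployed all of
2021 (4,745 trap days); expected monthly visits (3, 3, 15, 40, 60, 45, 25,
20, 18, 15, 10, 6 — ≈ 260/year, May peak, near-silent hibernation months);
a diel mixture on the sun-time scale (bump 0.50 at +0.45 ± 0.10 just
before sunset, bump 0.25 at −0.40 ± 0.12 after sunrise, uniform floor
0.25) chosen so the sunset period dominates the night period while leaving
activity at all hours; a class mix dominated by adult males; behavior
repertoires in which subadults mostly investigate; adult-male bout
sequences drawn from a known ground-truth chain; and debarking restricted
to adult males between 1 April and 30 June with logistic probability
(intercept 1.5, Julian-date slope −0.02, sun-time slope 1.4). Bout
durations are lognormal with medians near published per-behavior means;
mark heights are above the shoulder line with probability 0.74 in
April–May and lower at the season edges.

Two calibration choices deserve explanation. The Julian-date and sun-time
slopes take the published signs and magnitude; the intercept is set so the
mean in-window debarking probability (~0.29) matches the ground-truth
chain's own share of debarking-containing sequences (~0.28). With the two
latent layers consistent, mating-window adult-male sequences are an
unbiased sample of the chain (outside the window sequences are conditioned
on never debarking, by construction), and the debarking frequency lands at
~7–8% of all visits, close to field observations. Second, the diel mixture
weights were sharpened from an initially flatter floor after the
seed-averaged emulation check showed sunset and night shares nearly tied;
the published pattern (marked sunset peak, depressed night activity)
supports the sharper mixture.

Each event receives a distinct (site, day) slot within its month, so
independence filtering at the default window never merges generated visits
— event counts are exactly reproducible from the ground-truth record.

**What it does not emulate:** individual identity and revisit dynamics,
spatial dependence between sites, detection failure, seasonal day-length
effects on *total* activity (only its diel placement), opportunistic
sampling, or class misidentification. A green pipeline test therefore
establishes that the analysis recovers injected structure from data of the
assumed form — not that the assumptions hold in any particular field
dataset.

### Recovery checks and their sample sizes

A 0.05 max-abs bound on transition-probability recovery needs on the order
of 2,000 pooled transitions; one synthetic year yields only ~65
mating-window adult-male sequences (~300 transitions), so the recovery test
pools 25 replicate years. Likewise the small 4-state chain is used where a
fixed 2,000-transition budget must constrain every row. Logistic recovery
is checked by direct simulation at n = 5,000 with 100 replicates (relative
bias < 10%, Wald coverage ≈ 95%), and the exposure-corrected χ² is
calibrated under 2,000 null simulations (type-I error 0.05 ± 0.015).

## Degenerate inputs and tie-breaks

- Events with no coded behavior become [START, END] sequences with a
  warning; chains where END is unreachable raise.
- A month with recorded events but zero trap days raises a
  data-consistency error; a month with zero events has RIC 0.
- Pruning at exactly the threshold retains the edge ("inferior to"
  semantics). DOT export orders nodes and edges lexicographically so equal
  models serialize byte-identically.
- The pipeline aborts on the first failing stage, names it, and removes
  partial outputs.

## Known limitations

- The independence window is a convention; published event counts cannot
  disambiguate the original clustering rule.
- The sun-relative time construction is one of several maps consistent
  with its verbal description; coefficients of the time covariate are
  comparable only within a fixed construction.
- Tukey p-values assume balanced-enough groups (the studentized-range
  approximation); group sizes here are equal by design (one value per
  event per behavior).
- The interaction row of the debarking model reports its computed p-value;
  no attempt is made to reproduce typographically corrupted table cells.
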
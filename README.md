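# ursamark

Analysis toolkit for camera-trap studies of marking behavior at brown bear
rubbing trees: ethogram-coded visit events, first-order Markov behavioral
sequences, solar-anchored activity patterns, and the inferential statistics
that go with them — plus a synthetic visit generator so the entire pipeline
can be exercised and validated without any field footage.

## Who this is for

Behavioral ecologists working with camera-trap video of marking sites
(rubbing trees, scratch posts, scent stations) who need to go from a
BORIS-style event log to publishable summaries: which sex/age classes
perform which behaviors, how behaviors chain together within a visit, and
how activity is distributed across the year and the day once survey effort
and day-length variation are accounted for.

## What it computes

**Events.** A *detection* is one camera trigger; detections at the same
site closer together than an independence window (default 30 min) are
merged into one *visit event*. Behaviors follow a five-category ethogram —
dorsal rubbing, facial rubbing, pedal marking, olfactory investigation, and
visual marking (debarking with claws/teeth, stored as `clawing`, `biting`,
`strip_removal`). Tabulations cover per-behavior event frequencies,
class × behavior-category percentages, bout-duration summaries
(zero-filled for absent behaviors), and the above/below-shoulder split of
visual mark heights.

**Sequences.** Each visit yields a behavior sequence (merged codes, runs
collapsed, bracketed by virtual START/END). Pooled adjacent pairs give a
first-order Markov chain: counts `c_ij`, probabilities
`p_ij = c_ij / Σ_j c_ij`, display pruning of edges with `p < 0.1`
(retained probabilities are not renormalized), entry/exit distributions,
and deterministic Graphviz DOT export.

**Solar time.** Sunrise/sunset from the NOAA solar-position equations at
the official zenith (90.833°). The day is tiled into four periods
(sunrise ±1 h, day, sunset ±1 h, night), and clock time is mapped onto a
sun-relative scale in [−1, +1] (solar midnight −1/+1, sunrise −0.5, solar
noon 0, sunset +0.5) so seasonal day-length variation drops out. Monthly
activity uses the relative independent capture index,
`RIC = 1000 × captures / camera-trap days`.

**Inference.** Exposure-corrected χ² goodness of fit
(`E_i = N·w_i/Σw`, exposure = trap days per month or summed period
durations), exact binomial post hocs (two-sided by tail doubling,
Bonferroni-adjusted), a binomial GLM (logit link) for debarking probability
against Julian date and sun time with AICc model comparison
(`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`), and one-way ANOVA with Tukey HSD
for behavior durations.

## Worked example

```python
import ursamark as um
from ursamark.synthetic import SyntheticConfig, generate_events

data = generate_events(SyntheticConfig(seed=7))       # one synthetic year
paths = data.write("sim")                             # events.csv, sites.csv
bundle = um.run_pipeline(um.RunConfig(
    events_path=str(paths["events"]),
    sites_path=str(paths["sites"]),
    out_dir="report",
))
```

With seed 7 this yields 264 independent visit events. The monthly RIC
series peaks in May (RIC 139.0 from 56 captures over 403 trap days) and is
lowest in February (2.7), and the exposure-corrected monthly χ² is 150.0 on
11 df (p ≈ 1.5e−26) — activity is far from uniform once the varying days
per month are accounted for. The period test gives observed counts
sunrise 28 / day 136 / sunset 55 / night 45; the 2-h sunset window holds
far more events than its share of the day predicts. The AICc table ranks
`intercept + sun_time + julian_date` first; its Julian-date coefficient is
−0.0121 (SE 0.0045, z = −2.7, p = 0.007), i.e. the odds of debarking
decline as the season advances within the mating window, while the positive
`sun_time` coefficient (1.59, p = 0.03) shifts debarking toward the
evening. The pruned sequence diagram (`report/diagram.dot`) shows rubbing
as the entry behavior (START→rubbing 0.90) and debarking returning to
rubbing with probability 0.84.

The same run is available from the shell:

```bash
ursamark simulate --seed 7 --out sim
ursamark report --events sim/events.csv --sites sim/sites.csv --out report
```

Other subcommands (`tabulate`, `sequences`, `temporal`, `test`, `glm`,
`fixtures`) expose the individual stages.

## Acceptance script

`scripts/acceptance.py` regenerates a synthetic year from the given seed,
runs the full pipeline on it end to end, and writes its result JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/ursamark/events.py` — data model, CSV dialects, independence
  filtering, tabulations
- `src/ursamark/sequences.py` — behavioral sequences, `MarkovChain` /
  `MarkovChainResults`, pruning, DOT export
- `src/ursamark/solar.py` — sunrise/sunset, diel periods, sun-relative
  time, RIC, actogram table
- `src/ursamark/inference.py` — χ² GOF with exposure, exact binomial post
  hocs, `DebarkingModel`, ANOVA + Tukey
- `src/ursamark/synthetic.py` — the visit generator and its ground-truth
  record
- `src/ursamark/pipeline.py`, `src/ursamark/cli.py` — report bundle and CLI
- `docs/methods.md` — modelling assumptions, defaults, and numerical
  choices
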
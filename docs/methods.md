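# Methods

## The inferential model

Within one case (one participant's pooled deployments, one physiological
parameter) the occurrence means form an unbalanced one-way layout over up
to six task levels. The target quantities are the pairwise differences of
task-level means — the least-square differences (LSDs) of the one-way
model, written `mean(A) − mean(B)` for a contrast `A-B`. Because the
occurrence means are not assumed normal (and in practice are not), the
sampling distribution of each LSD is obtained by case resampling
stratified by task: a replicate redraws every task stratum with
replacement at its original size, so each replicate has exactly the
original per-task sample sizes — important for a design where one task may
contribute 174 means and another 3. A replicate's level means yield one
draw of every pairwise difference; over B replicates the equal-tailed
percentile interval at confidence level L brackets each LSD, and a pair is
declared significant exactly when zero falls outside its interval. No
p-values exist in this framework.

The repeated-measures framing of the design degenerates here: a case
contains a single participant, so the subject factor has one level and the
model reduces to the one-way ANOVA above. Individuals are never pooled —
resting levels and task responses differ too much between people for a
population-level contrast to mean anything at this sample size.

The default confidence level is 99.98%. With ~405 comparisons across a
full campaign, per-comparison level α = 0.0002 keeps the family-wise error
rate at `1 − (1 − 0.0002)^405 ≈ 7.78%` under independence; the reporting
module computes this arithmetic for any table.

### Bootstrap parameters

- `n_replicates` (default 100,000): the 0.01% tails of a 99.98% interval
  then rest on ≥ 10 order statistics per tail. Running with fewer
  replicates than the tail mass can resolve is permitted but warned about:
  the percentile endpoints then interpolate toward the replicate extremes,
  which widens intervals and makes the test *more* conservative, never
  less. (A hard error is reserved for `n_replicates < 2`.)
- `ci_level` (default 99.98%): per-comparison confidence, percent.
- `resampling_scheme`: `"stratified-by-task"` (default, preserves per-task
  n) or `"pooled"` (ignores strata; a sensitivity variant in which a task
  can vanish from a replicate).
- Percentiles use linear interpolation (`numpy.percentile` default);
  ties and degenerate strata (n = 1) are legal — a stratum of one value
  resamples to itself and contributes zero bootstrap variance.

### Calibration, honestly stated

The percentile interval of a mean difference at small stratum sizes omits
the small-sample t correction and uses the 1/n plug-in variance, so it is
mildly anti-conservative: at n = 15 per stratum and L = 95% the true
per-pair type-I rate is `2·P(t₂₈ > 1.96·√(14/15)) ≈ 0.069`, not 0.050,
which the test suite measures and which matches an independent naive-loop
bootstrap. At the operating level of 99.98% with a few thousand replicates
the deep-tail interpolation described above dominates and the realized
rejection rate on null data falls well below the nominal 0.0002 band — the
procedure as used is conservative, which is the stated design intent.

## Case assembly

Occurrence means (all tasks, baseline included) are pooled per deployment;
each pair of a participant's deployments is compared with a two-sided
two-sample Kolmogorov–Smirnov test (asymptotic null distribution by
default, exact available). One comparison (two deployments) runs at
α = 0.05; the three comparisons of a three-deployment participant run at
α = 0.017 each; beyond three (not a study configuration) a Bonferroni
`0.05 / C(n,2)` generalization applies. Deployments joined by
non-significant pairs pool into one case.

KS non-significance is not transitive, so pooling is defined as maximal
cliques of the non-significance graph, assigned greedily by descending
combined sample size with a deterministic ID < HI1 < HI2 tie-break;
leftover deployments become singleton cases. The cliques of a 3-node graph
are trivial, but the rule is stated so the behaviour is deterministic in
every configuration. Note the KS statistic is discrete: at n = m = 30 the
attainable level just below 0.05 is ≈ 0.034, so the pooling test runs
slightly conservative at realistic sample sizes.

## Ingest conventions

- Task intervals are half-open `[start, end)`; the boundary second belongs
  to the later task. Minute-scale task logging cannot adjudicate
  boundaries, so one convention is fixed rather than guessed per file.
- The HR-confidence filter removes the entire record (HR, RR and HRV) when
  confidence is strictly below the threshold (default 50%); the boundary
  value is kept. The device reports confidence for the system as a whole,
  so per-channel filtering would claim knowledge the instrument does not
  provide.
- A per-file `clock_offset_s` manifest field (default 0) shifts log times
  to absorb a known logger/device clock offset.
- Occurrences are maximal same-label runs of surviving records within one
  EVA. Records removed by the confidence filter do not split an
  occurrence — the occurrence is the task episode, not the data run;
  splitting on dropouts would inflate occurrence counts and re-introduce
  the dependence the aggregation exists to remove. Consequence: if an
  entire intervening episode of a *different* task is removed by the
  filter, its same-label neighbours merge; this is undecidable from
  filtered data and accepted.
- HRV occurrence means require ≥ `hrv_min_samples` valid readings
  (default 60, one minute at 1 Hz — the variability estimator needs a
  window of beats, and sub-minute windows are noise). HR/RR accept
  single-second occurrences.

## The synthetic-data generator

The generator emulates the measurement structure the analysis assumes, not
the physiology itself. Per second, each parameter is

```
value(t) = baseline_mu[participant] (+ deployment_shift)
         + task_effect[task(t)] + carryover(t) + AR(1) noise
```

- **Campaign shape** (defaults): 8 participants — two in all three
  deployments (ID, HI1, HI2), two in two, four in one — at 2 EVAs per
  participant-deployment pair: 28 streams, the study's footprint.
- **Baselines**: drawn once per participant from resting ranges
  (HR 62–82 bpm, RR 12–17 breaths/min, HRV 45–75 ms) unless given.
- **Task effects** (defaults, HR / RR / HRV): ET +28 / +4.5 / −14,
  BR +26 / +4 / −13, BS +18 / +2.5 / −9, EO +12 / +2 / −6,
  EI +10 / +1.5 / −5, Base 0 — strenuous tasks highest, baseline lowest,
  HRV falling under load, magnitudes in the range the pairwise tables of
  such campaigns report.
- **Schedule** (`"auto"`): baseline rest first (~30 min seated for the ID
  protocol, ~10 min vehicle transit for HI), then traverse/observe
  alternation, then two instrument–break–bag station blocks; segment
  durations are drawn per EVA from realistic ranges (1–8 min).
- **Noise**: AR(1) with ρ = 0.9 and stationary SDs 3 bpm / 1.5 brpm /
  8 ms. AR(1) is the minimal model of the serial dependence the analysis
  is built to withstand; an optional standardized-lognormal innovation
  switch provides right-skew without asserting a distributional claim.
- **Carry-over**: after a strenuous task (ET, BR) its effect decays
  exponentially (half-life 60 s by default, 0 disables) instead of
  vanishing — recovery bleeds into the next task's readings. Calibration
  tests disable it.
- **Measurement artifacts**: HR-confidence dropouts (5%/s drawn below 50,
  the rest in 75–100), 120 s HRV warm-up gap, and task-log transitions
  jittered by U(−30, +30) s then rounded to whole minutes, as a human
  logger timestamps. Rounding adds up to 30 s beyond the jitter bound, so
  a logged boundary sits within `label_jitter_s + 30 s` of truth; segments
  collapsed to nothing by jitter drop out of the log.

What the generator does **not** emulate: waveform-level physiology,
motion artifacts correlated with task, circadian drift, device firmware
quirks, or between-day fatigue. Passing recovery tests therefore shows the
*pipeline* is correct under the stated statistical structure — not that
the structure captures everything in real field data.

## Determinism

Every stream derives its RNG from `(campaign seed, participant,
deployment index, EVA index)` and every bootstrap case from `(seed,
parameter index, case id)`, so outputs are independent of iteration order
and a fixed seed reproduces every file byte-for-byte.

## Problem sizes in the validation suite

The statistical checks run at sizes chosen to keep Monte-Carlo error well
below the decision margins: 2,000 null cases × 2,000 replicates for
type-I calibration (30,000 pair tests, binomial SE ≈ 0.0015), 500 cases
for effect recovery at 5 noise-SD separations, 1,000 participants per
case-assembly scenario, and 100,000 replicates against exhaustive
≤ 4⁴×4⁴ enumerations. The demo pipeline runs 20,000 replicates; a
production run at the default 100,000 simply takes proportionally longer.

## Known limitations

- The greedy-clique pooling rule and the filter-gap merge rule are
  conventions for situations the underlying procedure leaves unspecified;
  both are deterministic and documented above.
- Published summary tables of this kind occasionally print percentages
  inconsistent with their own fractions (e.g. a 7/10 printed as 58%); the
  reporting module always emits the exact counts alongside round-half-up
  percentages and makes no attempt to reproduce such inconsistencies.
- BCa intervals are not implemented; the percentile interval is the
  documented method and the conservative operating level is the intended
  error-control mechanism.
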
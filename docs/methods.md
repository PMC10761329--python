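# Methods

## Scope

`actidelta` implements an event-locked case–crossover analysis of wrist
actigraphy around cluster-headache attacks: an activity-index (AI) statistic
computed from raw tri-axial acceleration, off-body detection, attack/interval
eligibility with matched non-attack intervals, percentile-delta features, and
paired Wilcoxon inference with Bonferroni correction. Because recordings of
this kind are patient data and not publicly distributable, the package ships a
first-class synthetic-data generator that emulates the study's data structure;
every downstream stage is exercised against it.

## Activity index

Per window of duration H (default 1 s, i.e. 32 samples at 32 Hz):

AI = sqrt(max(0, (1/3)·Σ_m (σ²_m − σ²_i))), m ∈ {x, y, z},

with σ²_m the per-axis variance over the window and σ²_i a systematic
device-noise variance, 0 by default (this device class has negligible
systematic noise; the max(0,·) guard is inert at σ_i = 0 but kept so the
general form stays correct when σ_i > 0 is configured). The statistic is
location-invariant — gravity and any constant offset cancel — non-negative,
axis-permutation-invariant, and |c|-homogeneous at σ_i = 0.

Choices where more than one convention exists:

* **Variance estimator**: unbiased sample variance (n−1) by default; the
  population (n) estimator is available. All worked values in the tests are
  recomputed by an independent per-window loop under the configured estimator.
* **Window partitioning**: non-overlapping, clock-aligned windows (tiling, not
  sliding); a trailing partial window is dropped.
* **Partial data**: a window contributes only if all its samples are present
  and on-body (`min_valid_fraction_per_window = 1.0`, configurable); a minute
  contributes only with ≥ 30 valid seconds. Both thresholds are recorded in
  the run log.
* **Numerics**: two-pass (mean-centered) variance with float64 accumulation,
  stable when the ~1 g gravity offset dominates the within-window noise;
  the vectorized kernel matches the naive loop to 1e-12 on float64 input.

## Off-body detection

Only the accelerometer channel is in scope, so wear detection is a
variance-floor rule: windows of `window_minutes` (5 min) sliding at a 1-min
hop are candidate off-body when the per-axis SD is below `sd_threshold`
(0.004 g) on all three axes; covered minutes form runs, runs separated by
less than `merge_gap_minutes` (2 min) are merged and runs shorter than
`min_offbody_minutes` (15 min) are discarded. The threshold sits between the
off-body noise floor (~0.001 g) and the worn-at-rest floor (~0.005 g, with
posture shifts adding between-minute variance on top). Gapped samples carry
no wear information: windows without enough present samples make no wear
decision, so detection is idempotent and an all-gap stretch keeps its wear
status. Exclusion happens before data ratios and AI are computed.

## Eligibility and matched intervals

* Daytime rule: the attack interval (half-open, minute precision) must not
  intersect any nightly [23:00, 07:30) window, in local wall-clock time.
* Data ratio: fraction of expected grid samples in the interval that are
  present and on-body; eligibility needs ≥ 0.75, boundary inclusive.
* Matched non-attack windows: same wall-clock range on every other study day
  of the same day-type (weekday vs weekend, from the onset date; windows
  crossing midnight inherit the onset date's type), excluding holidays,
  requiring every point of the window to be ≥ 24 h (boundary inclusive) from
  the start and end of every registered attack, and the same ≥ 75% ratio.
  All matches are pooled into one comparison distribution; the pooled volume
  must be at least the attack duration, otherwise the attack is excluded
  (`insufficient_pool`). Holidays exclude candidate days only; an attack on a
  holiday is retained.
* Onset-relative bins: seven bins from −3 h to +3 h anchored at onset, each
  matched by the same construction on the bin's clock range and requiring the
  75% ratio on both sides. Two per-bin exclusions apply: (a) strict daytime —
  a bin overlapping nighttime is dropped (configurable to lenient, since it is
  ambiguous whether such bins should inherit the attack-level rule); (b) a bin
  that overlaps a *different* registered attack is dropped — with several
  attacks per day a "pre-ictal" bin would otherwise contain a neighbouring
  attack and contaminate the contrast.

## Percentile deltas and inference

Δ_q = AI_q(attack) − AI_q(pooled matched), q ∈ {25, 50, 75, 90}; negative
deltas mean reduced movement during the attack. (The alternative sign
convention — subtracting the attack value *from* the matched value — appears
in prose descriptions of this design; the adopted convention is the one under
which reported negative deltas mean reduced attack-time activity, and it is
fixed package-wide.)

**Quantile rule.** Attack windows are short (median ≈ 30 per-minute values)
while the pooled matched sample is roughly an order of magnitude larger. The
classic type-7 "linear" quantile underestimates upper quantiles at small n,
so pairing a short-window p90 against a large-pool p90 produces a systematic
negative Δ offset under the null — enough to inflate the signed-rank
family-wise error severalfold in simulation. The delta analyses therefore use
the median-unbiased linear-interpolation rule (Hyndman & Fan type 8) by
default; `percentile_features` itself defaults to the plain linear rule, and
both are available everywhere (`quantile_method`).

**Wilcoxon signed-rank**, two-tailed. Exact null distribution (subset-sum
convolution over rank assignments, equivalent to enumerating all 2^N sign
patterns) for N ≤ 25 with no ties and no kept zeros; otherwise a normal
approximation with mid-ranks, tie correction, and a 0.5 continuity
correction. Zeros are dropped by default (classic rule); the Pratt rule is
available. All-zero input yields p = 1 with a warning. Agreement with an
independent reference implementation is tested to 1e-10.

**Bonferroni**: adjusted p = min(1, m·p); m = 4 for the whole-attack analysis
(the four percentiles), and m = number of tests actually performed for the
onset-relative analysis; both overridable.

## Synthetic-data generator

The generator emulates what the analysis assumes about real recordings:

* **Latent activity**: a first-order semi-Markov chain over
  {rest, low, moderate, high} at minute resolution. Hourly profiles give
  target state *occupancies* (night ≈ 95% rest; daytime 15/25/25/35%;
  morning/evening shoulders in between), converted to bout entry
  probabilities by the mean dwell times (8/4/2/1 min) so realized occupancy
  matches the profile. Movement-state SDs are 0.03/0.10/0.30 g with a
  mean-one uniform per-minute intensity jitter (±50%), giving a continuous,
  well-populated upper intensity band; rest stays at the 0.005 g device noise
  floor. Minutes-scale bouts and a smooth intensity continuum matter beyond
  realism: with long bouts or a gap-ridden 4-state mixture, the sample p90 of
  a short window is not comparable to a pooled p90 and the null calibration
  of the downstream test breaks.
* **Signal**: per-sample acceleration = unit-norm gravity vector (slow
  orientation random walk, constant within a minute, frozen during off-body
  segments) + Gaussian noise at the latent state's SD, clipped to ±2 g.
* **Attacks**: durations ~ N(37, 25²) min clipped to [15, 180]; placed on a
  contiguous "bout" block of days (~2.5 attacks/day), onsets uniform over
  08:00–22:00, non-overlapping; a configurable fraction can be forced into
  the nighttime window for filter tests. The bout structure reflects how
  chronic cluster headache presents (several attacks per day in active
  periods) and is what leaves attack-free days for the ≥ 24 h matching rule.
  Intensity (2–5) and acute-treatment labels are drawn independently of the
  movement effect; a coupling knob (`treatment_effect_map`) exists for
  stratified-analysis tests.
* **Attack effect**: a multiplier on the high-state occupancy from
  `preictal_effect_minutes` (30) before onset through attack end — < 1
  suppression, > 1 agitation, 1 exactly null (the effect window then leaves
  no trace in the latent process).
* **Missingness**: streaming gaps as geometric bursts (mean 1 s) at a target
  rate (2%); daily ~40 min off-body "charging" windows in the late evening
  with near-zero noise and frozen orientation. Ground truth (latent states,
  gap and off-body masks, attack/effect windows) is returned for
  parameter-recovery tests.

One seed drives everything; identical seed and configuration give
byte-identical output.

What the generator does **not** model: tremor/gait spectral structure,
postural transitions within a minute, device temperature or skin-contact
channels, day-level activity-level random effects (deliberately absent: a
shared day effect across pooled windows would correlate all deltas of a run,
which the paired design cannot absorb), smartphone registration latency, and
any within-attack temporal profile beyond a homogeneous effect window.
Passing tests therefore show the pipeline is correct and calibrated for data
with this covariance structure, not that real attacks behave this way.

## Monte-Carlo scales

The calibration and power ensembles simulate the full 21-day study at a
reduced 4 Hz sampling rate (1-s AI windows of 4 samples). Rate only changes
the per-second variance estimate's noise, which the per-minute average
absorbs; eligibility and inference are rate-independent. Study length is kept
at 21 days because the ≥ 24 h matching rule needs attack-free days to exist.
At this scale one replicate runs in about two seconds, so the shipped
ensembles (200 null seeds, 50 suppression seeds) complete in minutes.

Observed behavior at these conditions (recomputed by the test suite and
`scripts/acceptance.py` on every run): null family-wise rejection near the
nominal 0.05 within its binomial band; under suppression (effect 0.2),
negative median Δ at p75/p90 in ≈ all replicates, high p90 rejection power,
and the most negative onset-relative bin median at −30 min..0 or 0..+30 min.

## Degenerate inputs and edge rules

Empty eligible set → empty statistics tables plus a fully populated
eligibility ledger (every attack gets exactly one terminal status: nighttime
→ low_data_ratio → no_match → insufficient_pool → eligible). A single delta
gives an exact p of 1. Attacks overlapping each other in an event log are
accepted with a warning (registration data can contain them); explicitly
requested overlapping attack windows in the generator are rejected naming the
collision. E4-dialect files quantize to the dialect's native 1/64 g counts on
write; the generic CSV dialect round-trips floats to < 1e-9 g.
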
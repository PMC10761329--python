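# actidelta

Event-locked analysis of wrist actigraphy around cluster-headache attacks:
does movement, measured on the patient's wrist, drop or rise before and during
an attack?

Cluster headache attacks (15–180 min of severe unilateral pain) are classically
described with restlessness and agitation, which suggests wrist actigraphy
could serve as a digital biomarker of attacks. `actidelta` implements the full
measurement-and-inference chain needed to test that idea on raw tri-axial
accelerometry (32 Hz, ±2 g, Empatica-E4-style), together with a synthetic-data
generator that emulates multi-week recordings with embedded attacks, so the
whole chain is testable end to end without patient data.

## The measurement and the test

**Activity index.** From raw acceleration the absolute activity index over a
window H (1 s = 32 samples by default) is

    AI = sqrt( max(0, (1/3) · Σ_{m ∈ {x,y,z}} (σ²_m − σ²_i)) )

where σ²_m is the per-axis signal variance over the window and σ²_i a
systematic device-noise variance (0 for this device class). Second-level
values are averaged per minute; an interval of interest is then summarised by
the 25th/50th/75th/90th percentiles of its per-minute AI distribution.

**Matched non-attack intervals.** An attack qualifies when it is a daytime
attack (no overlap with 23:00–07:30) and at least 75% of its expected samples
are present and on-body (off-body wear is detected first by a variance-floor
rule and excluded). Its comparison distribution pools the same wall-clock
window on every other same-day-type (weekday/weekend), non-holiday study day
at least 24 h away from every attack, each match subject to the same 75% data
ratio.

**Inference.** Per attack and percentile q,

    Δ_q = AI_q(attack) − AI_q(matched pool)

so negative Δ means less movement during the attack. Across attacks each
percentile's Δ sample gets a two-tailed Wilcoxon signed-rank test (exact null
distribution for N ≤ 25 without ties), Bonferroni-corrected over the family of
four percentiles. A second analysis repeats this for seven onset-relative bins
from −3 h to +3 h around onset.

## Worked example

```bash
actidelta run --seed 11 --out report/
```

or equivalently from Python (as in `analysis/02_whole_attack_deltas.py`, which
uses a 21-day simulated participant whose attacks suppress high-intensity
movement from 30 min before onset):

```
13 of 15 attacks eligible
  p25: median Δ = -0.0101 g, Wilcoxon p_adj = 0.009766 (N = 13)
  p50: median Δ = -0.0695 g, Wilcoxon p_adj = 0.0009766 (N = 13)
  p75: median Δ = -0.1656 g, Wilcoxon p_adj = 0.0009766 (N = 13)
  p90: median Δ = -0.2313 g, Wilcoxon p_adj = 0.0009766 (N = 13)
  oxygen-treated only: N = 8, p90 p_adj = 0.03125
```

Reading: of the 15 registered attacks, 13 pass the daytime/data-ratio/matching
funnel. The attack-time AI distribution sits below its matched non-attack
distribution at every percentile, most strongly in the upper tail (p90,
Δ ≈ −0.23 g): high-intensity movement all but disappears during attacks, and
the effect survives Bonferroni correction. The onset-relative analysis
(`analysis/03_onset_relative.py`) localizes the drop to the −30 min..onset and
onset..+30 min bins, with near-zero deltas three hours away.

The numbered scripts under `analysis/` run the full study sequence: cohort
simulation with its eligibility funnel (01), whole-attack deltas (02),
onset-relative deltas (03), type-I-error calibration of the pipeline under a
null generator (04), and power/direction recovery under suppression (05).
Outputs land in `results/`.

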
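# Methods

This note documents the models and procedures implemented in `actvar`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## Data model

A participant's record is a gap-free 1-minute grid of MET values with a
per-minute sleep-state label (`awake`/`asleep`); missing observations are
explicit NaNs, never absent rows.  Analyses operate on daily aggregates:
the 24-hour, awake-state and asleep-state MET-minute sums of each
calendar day.  Sleep intervals that cross midnight are attributed to
calendar days minute-by-minute, so every 24-hour sum covers exactly 1440
minutes and `sum_awake + sum_asleep = sum_24h` holds identically.

## Preprocessing

- Duplicate timestamps keep the first occurrence (deterministic and
  order-stable; the choice is otherwise arbitrary).
- MET values below 0.9 — the device's sleeping metabolic floor — are
  treated as non-wear artifacts and dropped to missing.  The operation is
  idempotent and values exactly at 0.9 are retained.
- Participants with strictly more than 29 % missing MET minutes are
  excluded.  Missingness is computed *after* the floor drop: both absent
  samples and non-wear artifacts are unusable data.
- Sleep labels come from a per-day sleep summary; when a day carries
  several intervals only the longest is used.

## Gap filling

Four fillers are implemented:

1. **Phase-dependent (median week).**  For each half of the record (the
   first ⌈days/2⌉ and last ⌊days/2⌋ days; 103 days each for a 206-day
   record, with an odd middle day joining the first half), a 7×1440 grid
   holds the median observed value of each (day-of-week, minute) cell.
   Cells never observed are forward-filled from the preceding cell in
   (day-of-week, minute) lexicographic order starting Monday 00:00,
   wrapping from Sunday 23:59.  A missing minute takes its own half's
   cell value, keeping each fill in-sample with respect to its half.
2. **Linear interpolation** with a two-way limit direction, so leading
   and trailing gaps are filled by nearest-observation extension.
3. **Global personal median** of all observed values.
4. **Zero fill**, the no-fill equivalent when daily sums are the
   downstream statistic.

The evaluation harness injects one gap of each length in
{5, 10, 20, 40, 80, 160, 320, 640, 1280, 1440} minutes (3995 minutes
total when runs do not overlap) per participant at uniformly random
positions, overlaps permitted.  Each method's error is the sum of
absolute differences between prediction and held-out truth across all
participants; test indices whose true value was itself missing are
counted as indeterminate and excluded.  Within one gap length an
overlapped index is scored once; an index shared by runs of two different
lengths contributes to both lengths' (separate) experiments.  The
arg-min per length forms the policy, with ties broken in the fixed order
phase-dependent > linear > global-median > zero.  Sleep-state series are
evaluated on their 0/1 encoding with predictions rounded to {0, 1}
(0 = asleep, 1 = awake) before scoring.  When evaluation is skipped, the
default policy is linear for gaps ≤ 40 min and phase-dependent beyond
(sleep state: linear ≤ 320 min) — the structure the evaluation
reproduces on generated cohorts: short dropouts ride the smooth
minute-scale signal, whole missing days need the weekly phase structure.

## Variability metrics

For a positive daily-sum series p₁…pₙ (n ≥ 2):

- SD and CV use the sample (n−1) denominator, and IQRs use linear
  interpolation between order statistics — the defaults of the
  surrounding software ecosystem, stated here so they can be swapped.
- PV = 2 Σ_{i<j} (1 − min/max) / (n(n−1)); order-insensitive, in [0, 1).
- CDI = mean |ln(p_{i+1}/p_i)|; order-sensitive and scale-invariant.
- Modified Cohen d: |median difference| over the mean of the two IQRs;
  symmetric, zero iff the medians agree, undefined when both IQRs are 0.

## Group inference

The protocol is: Kruskal–Wallis H (tie-corrected, chi-square reference)
at a threshold of 0.05 divided by the number of planned comparisons in
the analysis family; if significant with more than two groups, a post hoc
Dunn z-test (tie-corrected, reported unadjusted — the Bonferroni
correction operates at the omnibus layer, and the denominators 3, 6, 12,
15, 30 are part of the protocol, carried explicitly by the pipeline
recipes); effect sizes only for significant pairs, with the larger-median
group named.  Degenerate input (every value identical) returns H = 0,
p = 1 with a warning rather than an exception.

The subpopulation test avoids comparing a population against its own
subset by comparing *daily cross-sectional IQRs*: one IQR of the 24-h
sums per study day for the whole group and for the group minus the
subpopulation, the two lists compared by Kruskal–Wallis.  The subgroup
"imparts variability" only when the whole population's IQRs are
significantly larger.  Lehr's rule n = 16 s²/Δ² (80 % power, α = 0.05)
converts the median daily IQR, used as the proxy for s, into per-group
sample sizes; results round to the nearest integer, the only rule
consistent with printed values such as 174.08 → 174 and 53.73 → 54.

## Weekend rhythms

Daily 24-h sums over a window of four consecutive fully covered calendar
months (the same window for everyone, avoiding the ragged study edges;
shorter records degrade gracefully to fewer months) are z-scored within
each individual — constant rows map to zeros with a warning — and
clustered with Ward-linkage agglomerative clustering into five groups.
The companion transform arctan(2z) bounds values for display.  A cluster
is labeled `weekend_high` when its members' mean z on Saturdays and
Sundays exceeds their weekday mean by more than 0.25 z-units,
`weekend_low` below −0.25, else `patternless`; participants inherit their
cluster's label.  The threshold replaces a visual heat-map read-off with
a reproducible rule; 0.25 separates generated amplitudes ≥ 0.25 from
noise at ~120 window days.  Weekend = Saturday + Sunday (configurable).

Note a structural point the clustering exposes: the split of patternless
individuals among their three clusters is noise-driven and unstable
under small perturbations, while the rhythm partition
(high/low/patternless) is highly stable — robustness checks should
therefore compare rhythm partitions, not raw cluster ids.

## Factor GAM

The model G(E(CDI)) = β₀ + f_sex + f_WR + f_age has an identity link,
Gaussian errors, categorical factor terms and no smoothing penalty, which
makes it exactly ordinary least squares on a sum-to-zero-coded design:
each factor's level effects sum to zero and a two-level factor reports
symmetric ± effects.  Pseudo-R² is the proportional reduction in deviance
(1 − RSS/TSS, as a percent); feature importance is the pseudo-R² drop on
refitting without a factor; term p-values use the Gaussian F
approximation.  Model selection fits main effects, +2-way and +2&3-way
interaction models (interaction orders whose cells are empty on small
cohorts are skipped with a warning), then drops factors whose main-effect
terms are not significant at 0.05; if nothing survives, the unpruned
main-effects model is reported rather than an empty one.

## Synthetic cohorts

The generator emulates the data-generating features the pipeline is
sensitive to, with defaults chosen once as study conditions:

- 1-minute sampling, default 206 days from 2020-04-01; one nightly sleep
  period (onset ~23:00 ± 60 min, duration 7.5 h ± 45 min, uniform);
  asleep minutes at 0.9 with occasional sleep movement; awake minutes
  composed of a diurnal profile, smooth (30-min moving-average) noise and
  0–2 Poisson-thinned exercise bouts of 20–60 min.
- Daily 24-h sums are drawn lognormal around a participant's latent level
  (median 1800 MET-min, between-person log-SD 0.05) and each day's awake
  minutes are scaled so the realized sum hits the draw exactly.  The
  day-to-day log-SD is σ = c·√π/2 for a target CDI c — the closed-form
  inverse of the half-normal mean of |ln ratios| for iid lognormal days,
  verified by Monte-Carlo.  Default targets vary by sex and age (female
  below male, declining in the oldest decades, 0.062–0.100) with a
  between-person jitter of SD 0.015, so demographic factors explain some
  but not all dispersion variance.
- Weekend phenotypes (defaults: 22 % high, 8 % low, 70 % patternless)
  shift weekend sums by a fractional amplitude (default 0.3).  This
  mechanically inflates the CDI of rhythmic participants — twice-weekly
  level jumps are real consecutive disparity — which reproduces the
  qualitative finding that weekend-rhythm groups are more variable,
  though more strongly than real cohorts show.
- Cyclic status is assigned (mostly to female participants under 60) but
  has no effect on generated activity by default; an optional 28-day
  sinusoidal modulation exists for power studies.
- Missingness is injected as contiguous runs at uniform random starts
  with Poisson counts per (length, expected-count) pair; the default mix
  (~1 % of minutes) combines many short dropouts with a few multi-hour
  gaps and about one whole missing day.

What the generator does **not** model: device-specific MET noise, heart
rate or steps, skin temperature, within-day autocorrelation beyond the
smooth noise, seasonality, or any real link between cyclic status and
activity.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and well-calibrated on data with known structure,
not that real cohorts will show any particular effect.

## Numerical and testing choices

- All randomness flows through `numpy` Generators seeded from explicit
  integers; identical (spec, seed) reproduce cohorts bit-for-bit, and a
  pipeline rerun with the same config reproduces every serialized output
  byte-identically (the manifest hash excludes the output path).
- Metric implementations are tested against independent loop oracles to
  1e-10 on a thousand random series; the rank tests against hand-rank
  computations on small all-unique samples; the GAM against a
  normal-equations oracle to 1e-8.
- Parameter-recovery tests allow the larger of ±30 % or twice the
  coefficient's sampling SE: the estimator is exact and unbiased, so
  recovery of effects whose magnitude sits below the design's noise floor
  is information-limited, not implementation-limited.
- Problem sizes in the test suite (cohorts of 8–100 participants, 28–206
  days) were chosen as the smallest sizes at which each property is
  cleanly expressed.
- Known limitations: the CDI calibration assumes iid lognormal days, so
  structured components (weekend shifts, the rare floor clamp when a
  drawn sum falls below the sleep+rest minimum) add variability beyond
  the target; the `patternless` cluster split is arbitrary (see above);
  and the 0.25 z-unit weekend threshold, while reproducible, has no
  claim to being the only defensible cutoff.
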
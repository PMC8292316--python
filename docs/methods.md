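# Methods

## Design overview

`chronodst` studies a natural experiment: the one-hour spring advance of
daylight-saving time, observed through consumer-wearable sleep events in a
cohort whose chronotype is proxied genetically.  The pipeline has four
stages — polygenic scoring, sleep-event classification, circular-statistics
aggregation, and the pre/post-transition comparisons — plus a synthetic
cohort generator that stands in for the restricted-access real data and
provides ground truth for every stage.

## Polygenic score and grouping

The score is the weighted additive model PGS = Σ S×G over variants, with S
the per-variant GWAS effect size for the effect allele and G ∈ {0, 1, 2}
the dosage.  QC order is fixed: externally flagged subjects (duplicates,
reported-sex mismatches — accepted as input flags, not computed, since
deriving them needs intensity/heterozygosity data the pipeline does not
model) are dropped first, then subjects with call rate < 0.99; variant call
rate (≥ 0.98) and MAF (≥ 0.005, autosomes only) are recomputed on the
retained subjects.  Scoring restricts to post-QC MAF ≥ 0.1 outside the MHC.

Choices worth noting:

* **MHC window** — chromosome 6, positions [25,000,000, 34,000,000),
  half-open: the region is named by convention rather than exact
  coordinates, so it is configurable (`QcThresholds.mhc_window`).
* **Missing dosages** are imputed with the variant's mean dosage
  (2 × allele frequency), matching common scorer behaviour and keeping the
  score defined for all subjects.
* **Standardization** uses the sample SD with the n−1 denominator; at
  cohort sizes of several hundred the choice is immaterial, but it must be
  pinned for bit-reproducibility.
* **Tertiles** are assigned by rank with ties broken by subject identifier
  (stable and reproducible); when n mod 3 ≠ 0 the middle group absorbs the
  remainder, so group sizes differ by at most 2.

## Event classification

A bout is a nighttime event iff its start time-of-day lies in
[18:00, 24:00) ∪ [00:00, 06:00) — 18:00 inclusive, 06:00 exclusive, so the
day is partitioned exactly (verified by a minute-resolution sweep of a full
week).  Bouts starting before 06:00 belong to the previous evening's
weekday.  The pre-week runs from the Saturday eight days before the
transition Sunday through the Friday before it, the post-week from the
transition Sunday through the following Saturday; for a 2019-03-10
transition these are March 2–8 and March 10–16.  Windows are computed from
the configured transition date, never hard-coded.

The duration filter (reject < 240 minutes asleep; exactly 240 is kept,
"less than four hours" being a strict rejection) is applied to minutes
asleep rather than the wall-clock span, which is inflated by the skipped
hour on the transition night.  Filtering precedes the same-weekday pairing
rule; pairing on unfiltered events would readmit subjects whose only event
on a weekday is a truncated bout.  Pairing is per weekday: a subject's
Monday events are kept iff the subject has at least one retained nighttime
Monday event in both windows.  Multiple qualifying bouts per subject-night
are all retained (no deduplication rule is imposed; the per-night means
absorb them).

Two conventions label work vs free nights: the profile convention
(work = Sun–Thu, free = Fri–Sat) for the asleep-time and daily-profile
analyses, and the social-jet-lag convention (work = Mon–Thu, free =
Fri–Sat, Sunday unlabelled).

## Circular statistics

Clock hours map to angles by θ = (t mod 24)·2π/24.  The circular mean is
the direction of the vector average; its resultant length r ∈ [0, 1]
measures concentration.  The von Mises concentration κ is estimated by the
standard three-regime closed-form inverse of the mean-resultant-length
function, with regime boundaries at r = 0.5 and r = 0.85; published
boundaries for the small/mid switch vary around 0.5–0.53 and the two
formulas differ by < 0.01 on that interval, well inside the approximation
error, so exact numerical parity with any particular toolbox is not
claimed.

The Watson–Williams multisample test uses the corrected statistic
F = g·(N−k)(ΣR_i − R) / ((k−1)(N − ΣR_i)) with g = 1 + 3/(8κ̂), where κ̂ is
estimated from the weighted mean resultant length ΣR_i/N pooled across
groups (the standard parametric construction).  When the pooled mean
resultant length falls below 0.45 the test's assumptions are doubtful; the
implementation warns but still returns a result, because sleep-timing data
are concentrated in practice and dispersed inputs arise only in synthetic
edge cases.  If every group is fully concentrated (r = 1) the F ratio is
0/0; coinciding group means return F = 0, distinct ones F = ∞.

No time-of-day quantity is ever averaged linearly; all such aggregation
routes through this module (a regression test feeds {23:30, 00:30} and
requires a midnight mean).

## Comparisons

* **Asleep time** (work nights, before vs after, per group): two-sample
  t-test on linear minutes.  Welch (unequal variances) is the default;
  a config switch restores pooled-variance Student's t.  The quantity is a
  duration, not a clock time, hence linear.
* **Daily profiles**: circular mean onset, offset and midpoint per
  (group, window, weekday); before/after shifts are wrapped signed
  differences in minutes.
* **Midpoint distributions** (morning vs evening, work or free nights):
  Watson–Williams on per-event circular midpoints, using every retained
  nighttime event before the transition Sunday without the pairing rule
  (pairing belongs to the before/after week design).  The four-hour filter
  is applied here too, with a switch to disable it.
* **Social jet lag**: per subject-window, circular mean free-night midpoint
  minus circular mean work-night midpoint, wrapped to (−720, 720] minutes,
  free-minus-work orientation (so a later free-night midpoint is positive).
  A subject enters a window iff it has ≥ 1 retained work-night and ≥ 1
  free-night event there; subjects need not appear in both windows.
  Before/after compared by two-sample t-test per group.

No multiple-testing correction is applied; results are reported as
unadjusted p-values at α = 0.05.

## Synthetic cohort generator

The generator emulates the study structure: ~800 genotyped subjects
(default `n_subjects=800`; tests and the acceptance experiment use 250 to
keep runs quick) wearing trackers over 15 nights — the Saturday eight days
before the transition through the Saturday after — with a March
spring-forward transition (default 2019-03-10).

**Genetics.** Variant allele frequencies are uniform on `maf_range`
(default (0.05, 0.5)); dosages are Binomial(2, p) per subject
(Hardy–Weinberg); effects are N(0, `effect_size_sd`).  A configurable
fraction of variants (default 5%) is placed inside the MHC window so the
scoring exclusion is exercised, and dosages go missing at rate 0.002,
giving sample call rates around 99.8% so that the 0.99 threshold excludes
the occasional subject, on the order of the ~1% seen in chip data.

**Latent chronotype.** midpoint = baseline + σ·√f·z + σ·√(1−f)·ε, with z
the standardized true score, σ = `midpoint_sd` (default 40 min — the total
between-subject SD) and f = `genetic_signal_fraction` (default 0.3).  The
squared score–midpoint correlation is then f in expectation for any
f ∈ [0, 1], and f = 1 makes the midpoint an exact affine function of the
score.  σ is deliberately the *total* SD rather than the residual SD, which
would leave f = 1 undefined.

**Schedule dynamics** (all in wall-clock minutes of midpoint delay):

* free (Fri/Sat) nights carry `free_night_delay` (default 50 min) for
  everyone — the source of a realistic ~50-min baseline social jet lag;
* post-transition nights start at 60 min (the advanced clock with an
  unshifted body) and decay piecewise-linearly over `adjust_days_morning`
  days (default 2) to a tertile floor: 0 (morning),
  `persistent_delay_evening` (evening, default 45 min), and half the
  evening floor for the middle tertile, whose dynamics are otherwise
  unspecified — interpolation is the least-commitment choice;
* on work nights only `work_night_floor_fraction` (default 0.2) of the
  floor is expressed.  This models duty schedules pinning work-night wake
  times: a persistently delayed clock shows up mostly on free nights.
  Without it, free and work nights would shift identically and
  post-transition social jet lag could not increase for the evening group
  — the defining signature of incomplete re-entrainment under social
  constraint.  The default yields an evening-group SJL increase of roughly
  +30 min with a flat morning group.

Nightly bouts centre `mean_sleep_duration` (420 min asleep, SD 30) plus a
constant 15 awake-in-bed minutes on the subject's midpoint plus the night's
delays and an N(0, 20 min) night-level jitter.  With probability
`short_event_rate` (0.03) the bout is cut short to 60–235 asleep minutes —
guaranteed to fail the four-hour filter — and with probability
`missing_night_rate` (0.08) the night is absent.  Timestamps are local
wall-clock, rounded to the minute.  The transition night is generated in
standard time and stamps at or after 02:00 on the transition Sunday are
shifted forward one hour, so a bout spanning the skipped hour prints a
wall-clock span 60 minutes longer than its true span while minutes
asleep/in bed carry the true elapsed time — matching how a device reports a
bout across the change.

All randomness derives from the single configured seed through three named
substreams (genotypes, latent traits, schedule); identical seed and
configuration give byte-identical outputs, file-level included.

**What the generator does not emulate:** light exposure, sleep stages,
realistic daytime naps, duration changes after the transition (minutes
asleep are drawn identically in both weeks, so the asleep-time comparison
is null on synthetic data by construction), seasonal/latitude effects, and
linkage disequilibrium between variants.  Passing recovery tests therefore
demonstrate that the pipeline correctly extracts the timing structure the
generator encodes — not that real cohorts behave this way.

## Numerical and interface choices

* Tie-breaks: tertile ranking by (score, subject identifier); stable sorts
  throughout.
* Wrapped signed differences map to (−12, 12] hours; the ±12 h boundary is
  resolved to +12.
* Degenerate inputs: empty circular samples raise; zero-resultant samples
  warn and report an undefined (NaN) mean; constant scores refuse
  standardization; cohorts emptied by QC raise rather than return empty
  frames; analysis cells with fewer than two observations raise an error
  naming the cell.
* Timestamps are serialized as ISO-8601 local wall-clock without timezone
  offsets; the skipped hour is handled explicitly, so offset-aware
  timestamps would only invite double conversion.
* Problem sizes: the test suite and acceptance experiment use 250-subject
  cohorts over 20 seeds and 1,000-replicate null calibrations, sizes at
  which every Monte-Carlo check's tolerance is comfortably wider than its
  sampling error.

## Known limitations

* The Watson–Williams correction uses a single pooled κ̂; with strongly
  unequal group concentrations the test is only approximate (the usual
  caveat of its parametric form).
* The piecewise-linear re-entrainment curve is a deliberate simplification;
  real adjustment is closer to exponential, but with nightly sampling over
  one week the two are not distinguishable and the linear form has
  interpretable parameters.
* Sex-mismatch/duplicate exclusions are pass-through flags; no genetic sex
  check is implemented.
* Scores are computed at a single p-value threshold (all variants); no
  clumping, LD modelling or ancestry components.
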
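# chronodst

Chronotype-stratified analysis of how sleep/wake timing adjusts to the
daylight-saving-time (DST) spring advance.

## The problem

When clocks jump forward one hour, wall-clock time changes while the
environment does not, and people's circadian clocks take days to re-entrain
— or fail to.  Whether someone adjusts quickly depends on their chronotype
(morningness vs eveningness).  `chronodst` implements, as a reusable and
fully tested pipeline, a natural-experiment design for studying this with
genotype data and consumer wearables:

1. **Genetic chronotype grouping.** A polygenic score for objectively
   measured sleep midpoint is computed with the weighted additive model
   *PGS = Σ S × G*, where *S* is the GWAS summary-statistic effect size for
   a variant's effect allele and *G* ∈ {0, 1, 2} the subject's dosage,
   restricted to common variants (MAF ≥ 0.1) outside the MHC after standard
   chip QC (sample call rate ≥ 0.99, then variant call rate ≥ 0.98 and
   MAF ≥ 0.005 on autosomes).  Standardized scores are split into tertiles:
   bottom third = morning group, top third = evening group.
2. **Sleep-event classification.** Device-recorded sleep bouts are
   nighttime events if they start between 18:00 and 06:00, attributed to
   the evening's weekday (a Monday 01:30 bout is a Sunday night).  Analysis
   windows are the week before the transition Sunday (Saturday–Friday) and
   the week after (Sunday–Saturday); bouts under four hours asleep are
   rejected, and a subject's weekday enters the before/after comparison
   only if observed on that weekday in both weeks.
3. **Circular statistics.** Clock times are projected to the circle
   (θ = t·2π/24; midnight = 0, noon = π) and aggregated with circular
   means; group mean directions are compared with the parametric
   Watson–Williams F-test, using the von Mises concentration estimate κ̂
   and its correction factor 1 + 3/(8κ̂).
4. **Social jet lag.** Per subject and window, the circular mean free-night
   midpoint (Fri–Sat) minus the circular mean work-night midpoint
   (Mon–Thu), in signed minutes — a behavioural readout of the mismatch
   between the body clock and the social schedule.

Because cohort wearable + genotype data of this kind are access-restricted,
the package ships a first-class **synthetic cohort generator**: genotypes
under Hardy–Weinberg proportions with a true additive polygenic signal,
latent sleep midpoints with a configurable genetically explained variance
fraction, and two weeks of nightly events with tertile-dependent
re-entrainment dynamics after the clock change (the morning tertile
re-entrains in a configurable number of days; the evening tertile keeps a
persistent delay, expressed mostly on free nights).  Every downstream claim
is therefore testable against known ground truth.

## Worked example

```bash
python examples/05_full_analysis.py
```

generates a 250-subject cohort (seed 5) and runs the whole pipeline,
printing among other things:

```
pre-transition midpoint separation (Watson-Williams):
  work nights: morning 2.56h vs evening 3.40h, F = 277.62, p = 4.05e-53
  free nights: morning 3.58h vs evening 4.32h, F = 113.58, p = 9.08e-24

social jet lag (free minus work midpoint, minutes):
  morning: 52 -> 51 min, t = 0.29, p = 0.7756
  evening: 45 -> 78 min, t = -10.38, p = 0.0000

evening-group Friday onset shift after the transition: 43.9 min (generator configured 45)
```

Read: the PGS-derived morning group indeed has earlier sleep midpoints than
the evening group; after the spring advance the evening group's social jet
lag jumps by ~30 minutes while the morning group's is unchanged; and the
configured 45-minute persistent evening delay is recovered from the
generated events to within noise.  The other examples
(`examples/01…04_*.py`) walk through the generator, the polygenic score,
event classification and the circular-statistics core one capability at a
time.

A thin CLI wraps the same calls: `chronodst simulate`, `chronodst pgs`,
`chronodst classify`, `chronodst analyze`, `chronodst all`.

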
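"""Synthetic study-cohort generator.

Builds a complete fake natural experiment: genotypes with a true additive
polygenic signal, per-subject latent sleep midpoints causally linked to that
signal, and two weeks of nightly wearable sleep events around a spring
daylight-saving transition with tertile-dependent re-entrainment dynamics.
Everything downstream (QC, scoring, event classification, circular analyses)
is testable against the configured ground truth without any external data.

Dynamics, in wall-clock minutes of delay added to a subject's midpoint:

* every Friday/Saturday ("free") night carries ``free_night_delay`` — the
  source of baseline social jet lag;
* on post-transition nights all groups start 60 min late (the advanced clock
  with an unshifted body) and decay piecewise-linearly over
  ``adjust_days_morning`` days to a group-specific floor: 0 for the morning
  tertile, ``persistent_delay_evening`` for the evening tertile, and half
  that for the middle tertile.  On work (Sunday-Thursday) nights only a
  ``work_night_floor_fraction`` share of the floor is expressed — duty
  schedules pin wake times, so a persistently delayed body clock shows up
  mostly on free nights, which is what drives post-transition social jet
  lag up in the evening tertile.

The night of the transition itself (the Saturday evening) is generated in
standard time and its timestamps falling on or after 02:00 on the transition
Sunday are shifted forward one hour, reproducing how a device stamps a bout
that spans the skipped hour: the printed wall-clock span exceeds the true
span by 60 minutes while minutes asleep / in bed reflect true elapsed time.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError
from .pgs import GenotypeSet, VARIANT_COLUMNS, assign_tertiles

__all__ = [
    "generate_genotypes",
    "generate_latent_chronotype",
    "generate_sleep_schedule",
    "generate_cohort",
    "SyntheticCohort",
]

EVENT_COLUMNS = ["subject_id", "start", "end", "minutes_asleep", "minutes_in_bed"]

# rng streams derived from the single configured seed
_STREAM_GENO = 1
_STREAM_LATENT = 2
_STREAM_SCHEDULE = 3


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _subject_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def generate_genotypes(config: CohortConfig) -> GenotypeSet:
    """Draw a dosage matrix under Hardy-Weinberg proportions.

    Each variant gets an allele frequency uniform in ``maf_range`` and
    dosages Binomial(2, p) per subject; effect sizes are N(0,
    ``effect_size_sd``).  A ``mhc_variant_fraction`` share of variants is
    placed inside the chromosome-6 MHC window (positions 25-34 Mb) so the
    scoring exclusion is exercised; the rest are spread over autosomes 1-22.
    Missing calls (NaN) occur at ``genotype_missing_rate``.  The true score
    (pre-missingness dosages times effect sizes) is stored on the returned
    set for the latent-chronotype step.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENO)
    n, m = config.n_subjects, config.n_variants

    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    effect = rng.normal(0.0, config.effect_size_sd, size=m) if config.effect_size_sd > 0 \
        else np.zeros(m)

    n_mhc = int(round(config.mhc_variant_fraction * m))
    chrom = rng.integers(1, 23, size=m).astype(str)
    pos = rng.integers(1, 200_000_000, size=m)
    if n_mhc:
        idx = rng.choice(m, size=n_mhc, replace=False)
        chrom[idx] = "6"
        pos[idx] = rng.integers(25_000_000, 34_000_000, size=n_mhc)
    alleles = rng.choice(list("ACGT"), size=(m, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")

    true_scores = dosages @ effect

    if config.genotype_missing_rate > 0:
        mask = rng.random(size=(n, m)) < config.genotype_missing_rate
        dosages[mask] = np.nan

    variants = pd.DataFrame({
        "variant_id": [f"rs{100000 + i}" for i in range(m)],
        "chrom": chrom,
        "pos": pos,
        "effect_allele": alleles[:, 0],
        "other_allele": alleles[:, 1],
        "effect_size": effect,
        "maf": np.minimum(p, 1 - p),
    })[VARIANT_COLUMNS]

    return GenotypeSet(dosages=dosages, variants=variants,
                       subjects=_subject_ids(n), true_scores=true_scores)


def generate_latent_chronotype(genotypes: GenotypeSet,
                               config: CohortConfig) -> np.ndarray:
    """Latent sleep midpoint per subject, clock hours.

    midpoint = baseline + sd*sqrt(f)*z + sd*sqrt(1-f)*eps, where z is the
    standardized true score, eps standard normal, sd = ``midpoint_sd`` (total
    SD, converted from minutes to hours) and f = ``genetic_signal_fraction``.
    The squared correlation between score and midpoint is then f in
    expectation, and f = 1 makes the midpoint an affine function of the
    score.
    """
    f = config.genetic_signal_fraction
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError("genetic_signal_fraction must be in [0, 1]")
    rng = _rng(config, _STREAM_LATENT)
    t = genotypes.true_scores
    if t is None:
        raise ValueError("genotype set has no true scores; use generate_genotypes")
    sd_t = t.std(ddof=1)
    z = (t - t.mean()) / sd_t if sd_t > 0 else np.zeros_like(t)
    sd_h = config.midpoint_sd / 60.0
    eps = rng.normal(size=t.size)
    return (config.baseline_midpoint
            + sd_h * np.sqrt(f) * z
            + sd_h * np.sqrt(1.0 - f) * eps)


# delay floor, as a fraction of persistent_delay_evening, by tertile
_FLOOR_FRACTION = {"morning": 0.0, "middle": 0.5, "evening": 1.0}
_DST_INITIAL_DELAY = 60.0  # the advanced clock, unshifted body


def _post_dst_delay(day_index: int, label: str, is_free_night: bool,
                    config: CohortConfig) -> float:
    """Wall-clock delay (minutes) on the ``day_index``-th night after the
    transition Sunday (Sunday = 0), piecewise-linear decay from 60 min to
    the tertile's floor over ``adjust_days_morning`` days.  On work nights
    the floor is attenuated by ``work_night_floor_fraction``."""
    floor = _FLOOR_FRACTION[label] * config.persistent_delay_evening
    if not is_free_night:
        floor *= config.work_night_floor_fraction
    if config.adjust_days_morning > 0:
        frac = max(0.0, 1.0 - day_index / config.adjust_days_morning)
    else:
        frac = 0.0
    return floor + (_DST_INITIAL_DELAY - floor) * frac


def generate_sleep_schedule(latent_midpoints: np.ndarray,
                            tertile_labels: np.ndarray,
                            config: CohortConfig) -> pd.DataFrame:
    """Nightly sleep events over the 15 nights around the transition.

    Nights are indexed by their evening date, from the Saturday eight days
    before the transition through the Saturday six days after.  Each
    subject-night centres a bout of ``mean_sleep_duration`` +/- noise on the
    subject's latent midpoint plus the night's delays and jitter; with
    probability ``short_event_rate`` the bout is cut short (uniform 60-235
    asleep minutes, guaranteed to fail a 4-h filter) and with probability
    ``missing_night_rate`` the night is dropped.  Timestamps are local
    wall-clock, rounded to the minute, honouring the skipped hour.
    """
    config.validate()
    if len(latent_midpoints) != len(tertile_labels):
        raise ValueError("latent_midpoints and tertile_labels length mismatch")
    rng = _rng(config, _STREAM_SCHEDULE)
    subjects = _subject_ids(len(latent_midpoints))
    dst = config.dst_date
    transition = datetime.combine(dst, datetime.min.time()) + timedelta(hours=2)
    night_dates = [dst + timedelta(days=d) for d in range(-8, 7)]

    rows: list[tuple] = []
    for sid, mid_h, label in zip(subjects, latent_midpoints, tertile_labels):
        for night in night_dates:
            if rng.random() < config.missing_night_rate:
                continue
            delay = 0.0
            is_free = night.weekday() in (4, 5)  # Friday, Saturday evenings
            if is_free:
                delay += config.free_night_delay
            day_index = (night - dst).days
            if day_index >= 0:
                delay += _post_dst_delay(day_index, str(label), is_free, config)
            jitter = rng.normal(0.0, config.onset_jitter_sd) \
                if config.onset_jitter_sd > 0 else 0.0
            midpoint_h = mid_h + (delay + jitter) / 60.0

            asleep = config.mean_sleep_duration
            if config.duration_sd > 0:
                asleep += rng.normal(0.0, config.duration_sd)
            asleep = max(asleep, 250.0)  # keep ordinary nights above the 4-h filter
            in_bed = asleep + config.wake_in_bed_minutes

            midnight = datetime.combine(night + timedelta(days=1),
                                        datetime.min.time())
            onset = midnight + timedelta(hours=midpoint_h, minutes=-in_bed / 2.0)

            if rng.random() < config.short_event_rate:
                asleep = rng.uniform(60.0, 235.0)
                in_bed = asleep + config.wake_in_bed_minutes
            end = onset + timedelta(minutes=in_bed)

            # the transition night is generated in standard time; stamps at or
            # after 02:00 on the transition Sunday read one hour later
            if night < dst:
                if onset >= transition:
                    onset += timedelta(hours=1)
                if end >= transition:
                    end += timedelta(hours=1)

            onset = _round_minute(onset)
            end = _round_minute(end)
            rows.append((sid, onset, end,
                         int(round(asleep)), int(round(in_bed))))

    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.sort_values(["subject_id", "start"], kind="stable").reset_index(drop=True)


def _round_minute(t: datetime) -> datetime:
    discard = timedelta(seconds=t.second, microseconds=t.microsecond)
    t -= discard
    if discard >= timedelta(seconds=30):
        t += timedelta(minutes=1)
    return t


class SyntheticCohort:
    """A generated cohort bundling genotypes, ground truth and sleep events."""

    def __init__(self, genotypes: GenotypeSet, latent_midpoints: np.ndarray,
                 true_groups: np.ndarray, events: pd.DataFrame):
        self.genotypes = genotypes
        self.latent_midpoints = latent_midpoints
        self.true_groups = true_groups
        self.events = events

    def true_group_map(self) -> dict[str, str]:
        return dict(zip(self.genotypes.subjects, self.true_groups))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Run the full generator: genotypes -> latent midpoints -> events.

    Tertile labels used for the schedule dynamics come from the TRUE score
    tertiles; the analysis pipeline re-derives groups from the estimated
    PGS, so the agreement between the two is itself a testable property.
    """
    genotypes = generate_genotypes(config)
    latent = generate_latent_chronotype(genotypes, config)
    true_groups = assign_tertiles(genotypes.true_scores, genotypes.subjects)
    events = generate_sleep_schedule(latent, true_groups, config)
    return SyntheticCohort(genotypes, latent, true_groups, events)
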
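"""Run configuration: cohort-generator settings, genotype QC thresholds and
the end-to-end analysis configuration, with YAML round-tripping.

Defaults follow the study design this package models: genotype QC at sample
call rate >= 0.99, variant call rate >= 0.98, MAF >= 0.005 on autosomes;
scoring restricted to MAF >= 0.1 outside the MHC; nighttime bouts shorter
than 240 minutes rejected; DST transition anchored on Sunday 2019-03-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import yaml

__all__ = ["CohortConfig", "QcThresholds", "RunConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """An invalid or inconsistent configuration value."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic study cohort.

    The defaults emulate the study structure: ~800 genotyped subjects wearing
    trackers over the two weeks around a March spring-forward transition,
    with a true additive polygenic signal on the latent sleep midpoint and
    tertile-dependent re-entrainment dynamics after the clock change.

    Attributes
    ----------
    n_subjects, n_variants:
        Cohort dimensions.
    maf_range:
        Variant minor-allele frequencies are drawn uniformly from this
        interval, which must lie within (0, 0.5].
    effect_size_sd:
        SD of the per-variant additive effect on sleep midpoint, in minutes
        of midpoint shift per effect allele.
    genetic_signal_fraction:
        Fraction of latent-midpoint variance explained by the true polygenic
        score (the r-squared of score on midpoint, in expectation).
    baseline_midpoint:
        Population mean sleep midpoint, clock hours.
    midpoint_sd:
        Total SD of the latent midpoint across subjects, minutes.
    mean_sleep_duration, duration_sd:
        Nightly minutes-asleep distribution.
    onset_jitter_sd:
        Night-to-night jitter of a subject's midpoint, minutes.
    dst_date:
        The Sunday the clocks advance.
    adjust_days_morning:
        Days the morning tertile takes to re-entrain after the advance.
    persistent_delay_evening:
        Residual post-transition delay of the evening tertile, minutes.
    free_night_delay:
        Friday/Saturday-night delay applied to every subject, minutes
        (the source of baseline social jet lag).
    work_night_floor_fraction:
        Fraction of a tertile's residual post-transition delay expressed on
        work (Sunday-Thursday) nights.  Work-night wake times are pinned by
        duty schedules, so an unshifted body clock shows up mostly on free
        nights; values < 1 make post-transition social jet lag grow for
        groups with a persistent delay.
    short_event_rate, missing_night_rate:
        Probability a night's bout is truncated below four hours / that a
        subject-night produces no event at all.
    wake_in_bed_minutes:
        Mean awake-in-bed minutes added on top of minutes asleep.
    mhc_variant_fraction:
        Fraction of variants placed inside the MHC exclusion window.
    genotype_missing_rate:
        Per-call probability of a missing dosage.
    """

    n_subjects: int = 800
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_size_sd: float = 1.0
    genetic_signal_fraction: float = 0.3
    baseline_midpoint: float = 3.0
    midpoint_sd: float = 40.0
    mean_sleep_duration: float = 420.0
    duration_sd: float = 30.0
    onset_jitter_sd: float = 20.0
    dst_date: date = date(2019, 3, 10)
    adjust_days_morning: int = 2
    persistent_delay_evening: float = 45.0
    free_night_delay: float = 50.0
    work_night_floor_fraction: float = 0.2
    short_event_rate: float = 0.03
    missing_night_rate: float = 0.08
    wake_in_bed_minutes: float = 15.0
    mhc_variant_fraction: float = 0.05
    genotype_missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.dst_date, str):
            self.dst_date = date.fromisoformat(self.dst_date)
        self.maf_range = tuple(self.maf_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_variants <= 0:
            raise ConfigurationError("n_subjects and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("short_event_rate", "missing_night_rate",
                     "genetic_signal_fraction", "mhc_variant_fraction",
                     "genotype_missing_rate", "work_night_floor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.adjust_days_morning < 0:
            raise ConfigurationError("adjust_days_morning must be >= 0")
        if self.dst_date.weekday() != 6:  # Monday == 0 ... Sunday == 6
            raise ConfigurationError(
                f"dst_date {self.dst_date} is not a Sunday; the analysis windows "
                "anchor on the Sunday transition"
            )


@dataclass
class QcThresholds:
    """Genotype QC and scoring thresholds.

    ``mhc_window`` is (chromosome, start, end) with half-open positions
    [start, end); the default is the conventional GRCh37 chromosome-6 window
    25-34 Mb (the region is named by convention, not by exact coordinates,
    so it is configurable).
    """

    sample_call_rate_min: float = 0.99
    variant_call_rate_min: float = 0.98
    maf_min_qc: float = 0.005
    autosomes_only: bool = True
    pgs_maf_min: float = 0.1
    mhc_window: tuple[str, int, int] = ("6", 25_000_000, 34_000_000)

    def __post_init__(self) -> None:
        self.mhc_window = tuple(self.mhc_window)  # type: ignore[assignment]
        for name in ("sample_call_rate_min", "variant_call_rate_min",
                     "maf_min_qc", "pgs_maf_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        _, start, end = self.mhc_window
        if not start < end:
            raise ConfigurationError("mhc_window start must be < end")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    dst_date: date = date(2019, 3, 10)
    qc: QcThresholds = field(default_factory=QcThresholds)
    min_event_minutes: float = 240.0
    profile_convention: str = "profile"   # Sun-Thu work / Fri-Sat free
    sjl_convention: str = "sjl"           # Mon-Thu work / Fri-Sat free, Sun unlabelled
    t_test: str = "welch"                 # or "student"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.dst_date, str):
            self.dst_date = date.fromisoformat(self.dst_date)
        if isinstance(self.qc, dict):
            self.qc = QcThresholds(**self.qc)
        if self.t_test not in ("welch", "student"):
            raise ConfigurationError(f"unknown t_test flavour {self.t_test!r}")
        if self.min_event_minutes < 0:
            raise ConfigurationError("min_event_minutes must be >= 0")
        if self.dst_date.weekday() != 6:
            raise ConfigurationError(f"dst_date {self.dst_date} is not a Sunday")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dst_date"] = self.dst_date.isoformat()
        d["qc"]["mhc_window"] = list(self.qc.mhc_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
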
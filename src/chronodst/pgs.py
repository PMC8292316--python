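"""Genotype QC and the objective-sleep-midpoint polygenic score.

The score follows the weighted additive model PGS = sum_v S_v * G_v, where
S_v is the GWAS summary-statistic effect size for variant v's effect allele
and G_v in {0, 1, 2} the subject's effect-allele dosage.  Scoring is
restricted to common variants (MAF >= 0.1) outside the MHC region, after a
conventional chip-QC pass (sample call rate, then variant call rate and MAF
recomputed on the retained samples, autosomes only).  Standardized scores are
split into tertiles: bottom third = morning group, top third = evening group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, QcThresholds

__all__ = [
    "GenotypeSet",
    "PgsResult",
    "QcReport",
    "EmptyCohortError",
    "qc_filter",
    "compute_pgs",
    "standardize_scores",
    "assign_tertiles",
    "score_cohort",
]

GROUPS = ("morning", "middle", "evening")

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele",
                   "other_allele", "effect_size", "maf"]


class EmptyCohortError(ValueError):
    """QC removed every subject (or no variants remain for scoring)."""


@dataclass
class GenotypeSet:
    """Dosage matrix plus variant metadata and summary-statistic weights.

    ``dosages`` is subjects x variants, float, values in {0, 1, 2} with NaN
    for missing calls.  ``variants`` is a DataFrame with columns
    ``variant_id, chrom, pos, effect_allele, other_allele, effect_size, maf``
    aligned to the matrix columns.  ``exclusion_flags`` carries externally
    supplied per-subject exclusion reasons (e.g. reported-sex mismatch,
    duplicate sample); such subjects are dropped as a pass-through first QC
    step, not re-derived here.  ``true_scores`` is populated only by the
    synthetic generator (the latent score before missingness) and is never
    used by the scoring pipeline.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    subjects: list[str]
    exclusion_flags: dict[str, list[str]] = field(default_factory=dict)
    true_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class QcReport:
    """Per-step removal counts from :func:`qc_filter`."""

    n_subjects_in: int = 0
    n_variants_in: int = 0
    removed_flagged: dict[str, int] = field(default_factory=dict)
    removed_sample_call_rate: int = 0
    removed_variant_call_rate: int = 0
    removed_variant_maf: int = 0
    removed_non_autosomal: int = 0
    n_subjects_out: int = 0
    n_variants_out: int = 0

    def format_log(self) -> str:
        lines = [
            f"QC input: {self.n_subjects_in} subjects, {self.n_variants_in} variants",
        ]
        for reason, n in sorted(self.removed_flagged.items()):
            lines.append(f"  removed {n} flagged subjects ({reason})")
        lines += [
            f"  removed {self.removed_sample_call_rate} subjects below sample call rate",
            f"  removed {self.removed_non_autosomal} non-autosomal variants",
            f"  removed {self.removed_variant_call_rate} variants below variant call rate",
            f"  removed {self.removed_variant_maf} variants below MAF threshold",
            f"QC output: {self.n_subjects_out} subjects, {self.n_variants_out} variants",
        ]
        return "\n".join(lines)


def _observed_maf(dosages: np.ndarray) -> np.ndarray:
    """Per-variant minor allele frequency from observed (non-missing) calls."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    return np.minimum(p, 1.0 - p)


_AUTOSOMES = {str(i) for i in range(1, 23)}


def qc_filter(genotypes: GenotypeSet,
              thresholds: QcThresholds | None = None) -> tuple[GenotypeSet, QcReport]:
    """Quality-control pass over a genotype set.

    Order is fixed: (1) drop externally flagged subjects, (2) drop subjects
    below the sample call-rate threshold, then (3) recompute per-variant call
    rate and MAF on the retained subjects and drop variants failing the
    variant thresholds or carrying a non-autosomal chromosome label (when
    ``autosomes_only``).  The returned variant table carries the post-QC
    observed MAF.  Raises :class:`EmptyCohortError` if no subject survives.
    """
    if genotypes.n_subjects == 0 or genotypes.n_variants == 0:
        raise EmptyCohortError("genotype set is empty")
    thresholds = thresholds or QcThresholds()
    report = QcReport(n_subjects_in=genotypes.n_subjects,
                      n_variants_in=genotypes.n_variants)

    keep_subject = np.ones(genotypes.n_subjects, dtype=bool)
    for i, sid in enumerate(genotypes.subjects):
        flags = genotypes.exclusion_flags.get(sid, [])
        if flags:
            keep_subject[i] = False
            for reason in flags:
                report.removed_flagged[reason] = report.removed_flagged.get(reason, 0) + 1

    call_rate = 1.0 - np.isnan(genotypes.dosages).mean(axis=1)
    below = keep_subject & (call_rate < thresholds.sample_call_rate_min)
    report.removed_sample_call_rate = int(below.sum())
    keep_subject &= ~below
    if not keep_subject.any():
        raise EmptyCohortError("QC removed every subject")

    dosages = genotypes.dosages[keep_subject]
    subjects = [s for s, k in zip(genotypes.subjects, keep_subject) if k]

    chrom = genotypes.variants["chrom"].astype(str).to_numpy()
    autosomal = np.isin(chrom, list(_AUTOSOMES))
    keep_variant = autosomal if thresholds.autosomes_only else np.ones(len(chrom), bool)
    report.removed_non_autosomal = int((~keep_variant).sum())

    vcall = 1.0 - np.isnan(dosages).mean(axis=0)
    fail_call = keep_variant & (vcall < thresholds.variant_call_rate_min)
    report.removed_variant_call_rate = int(fail_call.sum())
    keep_variant &= ~fail_call

    maf = _observed_maf(dosages)
    fail_maf = keep_variant & (maf < thresholds.maf_min_qc)
    report.removed_variant_maf = int(fail_maf.sum())
    keep_variant &= ~fail_maf

    variants = genotypes.variants.loc[keep_variant].copy().reset_index(drop=True)
    variants["maf"] = maf[keep_variant]

    out = GenotypeSet(
        dosages=dosages[:, keep_variant],
        variants=variants,
        subjects=subjects,
        exclusion_flags={},
        true_scores=(genotypes.true_scores[keep_subject]
                     if genotypes.true_scores is not None else None),
    )
    report.n_subjects_out = out.n_subjects
    report.n_variants_out = out.n_variants
    return out, report


def _in_mhc(variants: pd.DataFrame, window: tuple[str, int, int]) -> np.ndarray:
    chrom, start, end = window
    c = variants["chrom"].astype(str).to_numpy()
    pos = variants["pos"].to_numpy()
    return (c == str(chrom)) & (pos >= start) & (pos < end)


def compute_pgs(genotypes: GenotypeSet,
                thresholds: QcThresholds | None = None) -> np.ndarray:
    """Raw polygenic score per subject: sum over scoring variants of S x G.

    Scoring variants are those with post-QC MAF >= ``pgs_maf_min`` lying
    outside the MHC window.  Missing dosages contribute the variant's mean
    dosage (2 x allele frequency) in place of G, keeping the score defined
    for every subject.  Raises :class:`ConfigurationError` when no variant
    survives the scoring restriction.
    """
    thresholds = thresholds or QcThresholds()
    maf = genotypes.variants["maf"].to_numpy(dtype=float)
    keep = (maf >= thresholds.pgs_maf_min) & ~_in_mhc(genotypes.variants,
                                                      thresholds.mhc_window)
    if not keep.any():
        raise ConfigurationError("no variants retained for scoring "
                                 "(MAF and MHC restriction removed all)")
    G = genotypes.dosages[:, keep]
    S = genotypes.variants.loc[keep, "effect_size"].to_numpy(dtype=float)
    # mean-dosage imputation: allele frequency of the effect allele
    with np.errstate(invalid="ignore"):
        p = np.nanmean(G, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    G = np.where(np.isnan(G), 2.0 * p, G)
    return G @ S


def standardize_scores(raw: np.ndarray) -> np.ndarray:
    """Mean-centre and scale to unit sample SD (n-1 denominator)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("standardization needs at least 2 subjects")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate variance: scores are constant")
    return (raw - raw.mean()) / sd


def assign_tertiles(scores: np.ndarray, subject_ids) -> np.ndarray:
    """Morning / middle / evening labels from score tertiles.

    Subjects are ranked by score ascending, ties broken by subject identifier
    (a stable, reproducible rule).  The bottom n//3 are labelled morning and
    the top n//3 evening; when n is not divisible by 3 the middle group
    absorbs the remainder, so group sizes differ by at most 2.
    """
    scores = np.asarray(scores, dtype=float)
    ids = np.asarray(subject_ids)
    n = scores.size
    if n < 3:
        raise ValueError(f"tertile assignment needs at least 3 subjects, got {n}")
    if ids.size != n:
        raise ValueError("scores and subject_ids length mismatch")
    order = np.lexsort((ids, scores))  # score primary, identifier tie-break
    k = n // 3
    labels = np.full(n, "middle", dtype=object)
    labels[order[:k]] = "morning"
    labels[order[n - k:]] = "evening"
    return labels


@dataclass
class PgsResult:
    """Per-subject polygenic scores and tertile group labels."""

    subjects: list[str]
    raw: np.ndarray
    z: np.ndarray
    group: np.ndarray
    n_scoring_variants: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subjects,
            "raw_score": self.raw,
            "z_score": self.z,
            "group": self.group,
        })

    def group_map(self) -> dict[str, str]:
        return dict(zip(self.subjects, self.group))


def score_cohort(genotypes: GenotypeSet,
                 thresholds: QcThresholds | None = None) -> tuple[PgsResult, QcReport]:
    """QC, score, standardize and assign tertile groups in one call."""
    thresholds = thresholds or QcThresholds()
    clean, report = qc_filter(genotypes, thresholds)
    raw = compute_pgs(clean, thresholds)
    z = standardize_scores(raw)
    group = assign_tertiles(z, clean.subjects)
    maf = clean.variants["maf"].to_numpy(dtype=float)
    n_scoring = int(((maf >= thresholds.pgs_maf_min)
                     & ~_in_mhc(clean.variants, thresholds.mhc_window)).sum())
    return PgsResult(clean.subjects, raw, z, group, n_scoring), report
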
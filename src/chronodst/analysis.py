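"""Pre/post-transition analyses: asleep-time comparison, daily sleep
profiles, chronotype-group midpoint tests, and social jet lag.

All time-of-day aggregation routes through :mod:`chronodst.circular`; linear
quantities (minutes asleep, social-jet-lag minutes) are compared with
two-sample t-tests (Welch by default, pooled-variance Student on request)
and circular mean directions with the Watson-Williams test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from . import circular, events as ev, pgs as pgs_mod
from .config import RunConfig

__all__ = [
    "ComparisonResult",
    "InsufficientDataError",
    "asleep_time_comparison",
    "compute_sjl_table",
    "daily_profiles",
    "profile_shifts",
    "midpoint_distribution_test",
    "social_jetlag",
    "welch_t_from_summary",
    "run_full_analysis",
    "ReportBundle",
]

WORK_WEEKDAYS_PROFILE = ("Sunday", "Monday", "Tuesday", "Wednesday", "Thursday")


class InsufficientDataError(ValueError):
    """A required analysis cell is empty or too small."""


@dataclass
class ComparisonResult:
    """A two-sample comparison (t on linear data or Watson-Williams F).

    ``group_stats`` maps each cell name to ``{"mean": ..., "sem": ...,
    "n": ...}``; for circular comparisons the mean is a clock-hour circular
    mean and ``sem`` is NaN (dispersion is carried by the resultant length
    in ``extra``).
    """

    statistic: float
    statistic_kind: str  # "t" or "F"
    p_value: float
    group_stats: dict[str, dict] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "statistic_kind": self.statistic_kind,
            "p_value": self.p_value,
            "group_stats": self.group_stats,
            "extra": self.extra,
        }


def _ttest(x: np.ndarray, y: np.ndarray, flavour: str = "welch"):
    res = stats.ttest_ind(x, y, equal_var=(flavour == "student"))
    return float(res.statistic), float(res.pvalue)


def welch_t_from_summary(mean1: float, sem1: float, n1: int,
                         mean2: float, sem2: float, n2: int) -> tuple[float, float]:
    """Welch t and p reconstructed from printed means, SEMs and sizes.

    Useful for checking published comparisons when only summary statistics
    are available: t = (m1 - m2) / sqrt(sem1^2 + sem2^2) with
    Welch-Satterthwaite degrees of freedom.
    """
    v1, v2 = sem1**2, sem2**2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _cell(x: np.ndarray) -> dict:
    n = int(x.size)
    return {
        "mean": float(np.mean(x)) if n else float("nan"),
        "sem": float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "n": n,
    }


def asleep_time_comparison(classified: pd.DataFrame,
                           groups: dict[str, str],
                           weekdays=WORK_WEEKDAYS_PROFILE,
                           flavour: str = "welch") -> dict[str, ComparisonResult]:
    """Before vs after mean minutes asleep on work nights, per tertile group.

    Uses the analysis set (nighttime, duration-retained, same-weekday
    paired) restricted to ``weekdays`` (Sunday-Thursday by default).  The
    comparison is linear — minutes asleep is a duration, not a clock time.
    """
    df = ev.analysis_set(classified)
    df = df[df["assigned_weekday"].isin(weekdays)]
    glab = df["subject_id"].map(groups)
    out: dict[str, ComparisonResult] = {}
    for gname in ("morning", "evening"):
        sub = df[glab == gname]
        cells = {}
        for window in ("before", "after"):
            x = sub.loc[sub["dst_week"] == window, "minutes_asleep"].to_numpy(float)
            if x.size < 2:
                raise InsufficientDataError(
                    f"asleep-time cell ({gname}, {window}) has {x.size} events")
            cells[window] = x
        t, p = _ttest(cells["before"], cells["after"], flavour)
        out[gname] = ComparisonResult(
            t, "t", p,
            {w: _cell(cells[w]) for w in ("before", "after")},
            {"flavour": flavour},
        )
    return out


def _circ_cols(sub: pd.DataFrame) -> dict:
    onset = circular.circular_mean(circular.AngleSeries.from_hours(sub["start_hours"]))
    offset = circular.circular_mean(circular.AngleSeries.from_hours(sub["end_hours"]))
    mid = circular.circular_midpoint(sub["start_hours"].to_numpy(float),
                                     sub["end_hours"].to_numpy(float))
    midm = circular.circular_mean(circular.AngleSeries.from_hours(mid))
    return {"mean_onset": onset.mean_hours, "mean_offset": offset.mean_hours,
            "mean_midpoint": midm.mean_hours, "resultant_onset": onset.resultant_length,
            "n": len(sub)}


def daily_profiles(classified: pd.DataFrame,
                   groups: dict[str, str]) -> pd.DataFrame:
    """Circular mean onset/offset/midpoint per (group, window, weekday).

    One row per (morning/evening) x (before/after) x weekday cell of the
    analysis set; empty cells are reported with n = 0 and NaN means.
    """
    df = ev.analysis_set(classified)
    glab = df["subject_id"].map(groups)
    rows = []
    for gname in ("morning", "evening"):
        for window in ("before", "after"):
            for weekday in ev.WEEKDAY_ORDER:
                sub = df[(glab == gname) & (df["dst_week"] == window)
                         & (df["assigned_weekday"] == weekday)]
                row = {"group": gname, "window": window, "weekday": weekday}
                if len(sub) == 0:
                    row.update({"mean_onset": np.nan, "mean_offset": np.nan,
                                "mean_midpoint": np.nan, "resultant_onset": np.nan,
                                "n": 0})
                else:
                    row.update(_circ_cols(sub))
                rows.append(row)
    return pd.DataFrame(rows)


def profile_shifts(profiles: pd.DataFrame) -> pd.DataFrame:
    """After-minus-before shift in minutes per (group, weekday, measure),
    as wrapped signed circular differences."""
    rows = []
    for (gname, weekday), sub in profiles.groupby(["group", "weekday"], sort=False):
        before = sub[sub["window"] == "before"]
        after = sub[sub["window"] == "after"]
        if len(before) != 1 or len(after) != 1:
            continue
        row = {"group": gname, "weekday": weekday}
        for measure in ("mean_onset", "mean_offset", "mean_midpoint"):
            b = before[measure].iloc[0]
            a = after[measure].iloc[0]
            row[measure.replace("mean_", "shift_") + "_min"] = (
                circular.wrapped_diff_hours(a, b) * 60.0
                if np.isfinite(a) and np.isfinite(b) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def midpoint_distribution_test(classified: pd.DataFrame,
                               groups: dict[str, str],
                               night_class: str,
                               dst_date: date,
                               apply_duration_filter: bool = True) -> ComparisonResult:
    """Watson-Williams test of morning vs evening sleep midpoints pre-DST.

    Uses every retained nighttime event with assigned night strictly before
    the transition Sunday (not just the final pre-week, and without the
    same-weekday pairing rule, which belongs to the before/after comparison).
    ``night_class`` selects work or free nights under the profile convention
    (work = Sunday-Thursday, free = Friday-Saturday).
    """
    if night_class not in ("work", "free"):
        raise ValueError(f"night_class must be 'work' or 'free', got {night_class!r}")
    labelled = ev.label_work_free(classified, "profile")
    sel = labelled["is_night"] & (labelled["assigned_date"] < dst_date)
    if apply_duration_filter:
        sel &= labelled["retained_duration"]
    want_work = night_class == "work"
    sel &= (labelled["is_work_night"] == want_work).fillna(False).to_numpy(bool)
    df = labelled[sel]
    glab = df["subject_id"].map(groups)

    series, cells = [], {}
    for gname in ("morning", "evening"):
        sub = df[glab == gname]
        if len(sub) < 2:
            raise InsufficientDataError(
                f"midpoint test: {night_class}-night {gname} group has {len(sub)} events")
        mid = circular.circular_midpoint(sub["start_hours"].to_numpy(float),
                                         sub["end_hours"].to_numpy(float))
        s = circular.AngleSeries.from_hours(mid)
        series.append(s)
        summ = circular.circular_mean(s)
        cells[gname] = {"mean": summ.mean_hours, "sem": float("nan"),
                        "n": summ.n, "resultant_length": summ.resultant_length}
    ww = circular.watson_williams(series)
    return ComparisonResult(ww.f_statistic, "F", ww.p_value, cells,
                            {"df1": ww.df1, "df2": ww.df2,
                             "kappa_hat": ww.kappa_hat,
                             "night_class": night_class})


def compute_sjl_table(classified: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-subject, per-window social jet lag table.

    Work nights are Monday-Thursday and free nights Friday-Saturday (Sunday
    is unlabelled under this convention).  A subject enters a window iff it
    has at least one retained work-night and one retained free-night event
    in that window; subjects need not appear in both windows.  Social jet
    lag = circular mean free-night midpoint minus circular mean work-night
    midpoint, as a signed wrapped difference in minutes in (-720, 720].

    Returns (table, number of subject-windows excluded by the >=1/>=1 rule).
    """
    labelled = ev.label_work_free(classified, "sjl")
    sel = (labelled["is_night"] & labelled["retained_duration"]
           & labelled["dst_week"].isin(["before", "after"])
           & labelled["is_work_night"].notna())
    df = labelled[sel].copy()
    mid = circular.circular_midpoint(df["start_hours"].to_numpy(float),
                                     df["end_hours"].to_numpy(float))
    df["midpoint_hours"] = mid

    rows, n_excluded = [], 0
    for (sid, window), sub in df.groupby(["subject_id", "dst_week"], sort=True):
        work = sub[sub["is_work_night"] == True]  # noqa: E712 (nullable boolean)
        free = sub[sub["is_work_night"] == False]  # noqa: E712
        if len(work) == 0 or len(free) == 0:
            n_excluded += 1
            continue
        wmean = circular.circular_mean(
            circular.AngleSeries.from_hours(work["midpoint_hours"])).mean_hours
        fmean = circular.circular_mean(
            circular.AngleSeries.from_hours(free["midpoint_hours"])).mean_hours
        rows.append({
            "subject_id": sid, "window": window,
            "work_midpoint_hours": wmean, "free_midpoint_hours": fmean,
            "sjl_minutes": circular.wrapped_diff_hours(fmean, wmean) * 60.0,
            "n_work": len(work), "n_free": len(free),
        })
    table = pd.DataFrame(rows, columns=["subject_id", "window",
                                        "work_midpoint_hours", "free_midpoint_hours",
                                        "sjl_minutes", "n_work", "n_free"])
    return table, n_excluded


def social_jetlag(classified: pd.DataFrame,
                  groups: dict[str, str],
                  flavour: str = "welch") -> tuple[pd.DataFrame, dict[str, ComparisonResult], int]:
    """Social jet lag per subject plus its before/after t-test per group.

    See :func:`compute_sjl_table` for the per-subject definition.  Returns
    (per-subject table, per-group comparison, excluded subject-window
    count); an analysis cell with fewer than two subjects raises
    :class:`InsufficientDataError`.
    """
    table, n_excluded = compute_sjl_table(classified)
    comparisons: dict[str, ComparisonResult] = {}
    glab = table["subject_id"].map(groups) if len(table) else pd.Series(dtype=object)
    for gname in ("morning", "evening"):
        cells = {}
        for window in ("before", "after"):
            x = table.loc[(glab == gname) & (table["window"] == window),
                          "sjl_minutes"].to_numpy(float)
            if x.size < 2:
                raise InsufficientDataError(
                    f"social-jet-lag cell ({gname}, {window}) has {x.size} subjects")
            cells[window] = x
        t, p = _ttest(cells["before"], cells["after"], flavour)
        comparisons[gname] = ComparisonResult(
            t, "t", p, {w: _cell(cells[w]) for w in ("before", "after")},
            {"flavour": flavour})
    return table, comparisons, n_excluded


@dataclass
class ReportBundle:
    """Everything the end-to-end pipeline produces."""

    config: RunConfig
    qc_report: pgs_mod.QcReport
    pgs: pgs_mod.PgsResult
    counts: pd.DataFrame
    profiles: pd.DataFrame
    shifts: pd.DataFrame
    sjl_table: pd.DataFrame
    comparisons: dict
    log_lines: list[str] = field(default_factory=list)


def run_full_analysis(sleep_events: pd.DataFrame,
                      genotypes: pgs_mod.GenotypeSet,
                      config: RunConfig | None = None) -> ReportBundle:
    """End-to-end pipeline: QC -> PGS -> tertiles -> classification ->
    filters -> pairing -> the four analyses.

    ``sleep_events`` is a raw event table (as read by
    :func:`chronodst.io.read_sleep_events`), ``genotypes`` an un-QC'd
    genotype set.  Stage failures propagate with the stage name attached.
    """
    config = config or RunConfig()
    log: list[str] = []

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise type(e)(f"[{name}] {e}") from e

    result, qc_report = stage("pgs", pgs_mod.score_cohort, genotypes, config.qc)
    log.extend(qc_report.format_log().splitlines())
    groups = result.group_map()
    sizes = pd.Series(result.group).value_counts().to_dict()
    log.append(f"tertile groups: {sizes}")

    classified = stage("classify", ev.classify_events, sleep_events, config.dst_date)
    classified = stage("filter", ev.filter_min_duration, classified,
                       config.min_event_minutes)
    n_short = int((~classified["retained_duration"]).sum())
    log.append(f"events below {config.min_event_minutes:g} min asleep: {n_short}")
    classified = stage("pair", ev.pair_same_weekday, classified)
    in_window = classified["is_night"] & classified["dst_week"].isin(["before", "after"])
    log.append(f"nighttime in-window events: {int(in_window.sum())}; "
               f"paired analysis set: {int(classified['retained_paired'].sum())}")

    counts = stage("counts", ev.tabulate_counts, classified, groups)
    asleep = stage("asleep", asleep_time_comparison, classified, groups,
                   WORK_WEEKDAYS_PROFILE, config.t_test)
    profiles = stage("profiles", daily_profiles, classified, groups)
    shifts = profile_shifts(profiles)
    midpoint = {
        nc: stage("midpoints", midpoint_distribution_test, classified, groups,
                  nc, config.dst_date)
        for nc in ("work", "free")
    }
    sjl_table, sjl_cmp, n_sjl_excluded = stage("sjl", social_jetlag, classified,
                                               groups, config.t_test)
    log.append(f"subject-windows excluded from SJL (>=1/>=1 rule): {n_sjl_excluded}")

    comparisons = {
        "asleep_time": {g: r.to_dict() for g, r in asleep.items()},
        "midpoint_distribution": {nc: r.to_dict() for nc, r in midpoint.items()},
        "social_jetlag": {g: r.to_dict() for g, r in sjl_cmp.items()},
    }
    return ReportBundle(config, qc_report, result, counts, profiles, shifts,
                        sjl_table, comparisons, log)
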
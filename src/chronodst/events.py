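"""Sleep-event classification, windowing, duration filtering and pairing.

A device-recorded bout is a *nighttime* event if it starts between 18:00 and
06:00 (18:00 inclusive, 06:00 exclusive — the half-open rule makes the
day partition exact).  Bouts starting after midnight but before 06:00 are
attributed to the previous evening: a bout starting Monday 01:30 is a Sunday
nighttime event.  The pre-transition week runs from the Saturday eight days
before the transition Sunday through the Friday before it; the
post-transition week from the transition Sunday through the following
Saturday (for a 2019-03-10 transition: March 2-8 and March 10-16).

Filtering order is fixed: short bouts (< 4 h asleep) are rejected first,
then the same-weekday pairing rule is applied per weekday — a subject's
events on a given weekday are kept only if the subject has at least one
retained nighttime event on that weekday in both windows.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import ConfigurationError

__all__ = [
    "WEEKDAY_ORDER",
    "window_dates",
    "classify_events",
    "filter_min_duration",
    "pair_same_weekday",
    "label_work_free",
    "tabulate_counts",
    "add_totals",
    "analysis_set",
]

# Table-style ordering: the study week runs Sunday through Saturday
WEEKDAY_ORDER = ["Sunday", "Monday", "Tuesday", "Wednesday", "Thursday",
                 "Friday", "Saturday"]

NIGHT_EVENING_START = 18.0  # inclusive
NIGHT_MORNING_END = 6.0     # exclusive

PROFILE_WORK = {"Sunday", "Monday", "Tuesday", "Wednesday", "Thursday"}
SJL_WORK = {"Monday", "Tuesday", "Wednesday", "Thursday"}
FREE_NIGHTS = {"Friday", "Saturday"}


def window_dates(dst_date: date) -> tuple[date, date, date, date]:
    """(pre_start, pre_end, post_start, post_end) evening dates, inclusive."""
    if dst_date.weekday() != 6:
        raise ConfigurationError(f"dst_date {dst_date} is not a Sunday")
    return (dst_date - timedelta(days=8), dst_date - timedelta(days=2),
            dst_date, dst_date + timedelta(days=6))


def classify_events(events: pd.DataFrame, dst_date: date) -> pd.DataFrame:
    """Annotate raw events with night status, assigned weekday and window.

    Adds columns: ``start_hours`` / ``end_hours`` (wall-clock time of day),
    ``is_night``, ``assigned_date`` (the evening the bout belongs to),
    ``assigned_weekday``, and ``dst_week`` in {before, after, outside}.
    Rows with unparseable timestamps or end <= start raise a ``ValueError``
    naming the offending row indices (the I/O layer offers a lenient mode
    that drops and logs such rows before classification).
    """
    pre_start, pre_end, post_start, post_end = window_dates(dst_date)
    df = events.copy()

    for col in ("start", "end"):
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            parsed = df[col]
        else:
            parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        if parsed.isna().any():
            raise ValueError(
                f"unparseable or missing {col} timestamp at rows "
                f"{list(df.index[parsed.isna()])}")
        df[col] = parsed

    inverted = df["end"] <= df["start"]
    if inverted.any():
        raise ValueError(f"end <= start at rows {list(df.index[inverted])}")

    tod = (df["start"].dt.hour + df["start"].dt.minute / 60.0
           + df["start"].dt.second / 3600.0)
    df["start_hours"] = tod
    df["end_hours"] = (df["end"].dt.hour + df["end"].dt.minute / 60.0
                       + df["end"].dt.second / 3600.0)
    df["is_night"] = (tod >= NIGHT_EVENING_START) | (tod < NIGHT_MORNING_END)

    start_date = df["start"].dt.normalize()
    assigned = start_date.where(tod >= NIGHT_MORNING_END,
                                start_date - pd.Timedelta(days=1))
    df["assigned_date"] = assigned.dt.date
    df["assigned_weekday"] = assigned.dt.day_name()

    adate = df["assigned_date"]
    df["dst_week"] = np.select(
        [(adate >= pre_start) & (adate <= pre_end),
         (adate >= post_start) & (adate <= post_end)],
        ["before", "after"], default="outside",
    )
    return df


def filter_min_duration(events: pd.DataFrame,
                        min_minutes: float = 240.0) -> pd.DataFrame:
    """Flag events meeting the minimum asleep duration.

    Adds ``retained_duration`` = (minutes_asleep >= min_minutes): "less than
    four hours" is a strict rejection, so a bout of exactly 240 minutes is
    kept.  The filter applies to minutes asleep, not the wall-clock span,
    which is distorted on the transition night.
    """
    if min_minutes < 0:
        raise ConfigurationError("min_minutes must be >= 0")
    df = events.copy()
    df["retained_duration"] = df["minutes_asleep"] >= min_minutes
    return df


def pair_same_weekday(events: pd.DataFrame) -> pd.DataFrame:
    """Apply the same-weekday pairing rule, per weekday independently.

    Adds ``retained_paired``: True for a qualifying event (nighttime, inside
    a window, duration-retained) whose subject has at least one qualifying
    event on the same weekday in *both* windows.  The rule controls for
    rotating shift schedules: a subject contributes Monday nights only if
    observed on the Monday before and the Monday after the transition.
    """
    df = events.copy()
    qual = df["is_night"] & df["retained_duration"] & df["dst_week"].isin(
        ["before", "after"])
    q = df.loc[qual, ["subject_id", "assigned_weekday", "dst_week"]]
    present = (q.drop_duplicates()
                .groupby(["subject_id", "assigned_weekday"])["dst_week"]
                .nunique())
    both = set(present[present == 2].index)
    keys = list(zip(df["subject_id"], df["assigned_weekday"]))
    df["retained_paired"] = qual.to_numpy() & np.array(
        [k in both for k in keys], dtype=bool)
    return df


def label_work_free(events: pd.DataFrame, convention: str) -> pd.DataFrame:
    """Label nights as work or free under the requested convention.

    ``profile``: work = Sunday-Thursday, free = Friday-Saturday (the daily
    sleep-profile and asleep-time analyses).  ``sjl``: work = Monday-Thursday,
    free = Friday-Saturday, Sunday unlabelled (the social-jet-lag analysis).
    Adds a nullable-boolean ``is_work_night`` (NA = unlabelled).
    """
    if convention == "profile":
        work = PROFILE_WORK
    elif convention == "sjl":
        work = SJL_WORK
    else:
        raise ConfigurationError(f"unknown work/free convention {convention!r}")
    df = events.copy()
    wd = df["assigned_weekday"]
    values = np.select([wd.isin(list(work)), wd.isin(list(FREE_NIGHTS))],
                       [True, False], default=None)
    df["is_work_night"] = pd.array(values, dtype="boolean")
    return df


def analysis_set(events: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the before/after weekly analyses: nighttime, in-window,
    duration-retained and same-weekday paired."""
    return events[events["retained_paired"]]


def tabulate_counts(events: pd.DataFrame,
                    groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-weekday counts of nighttime events by window and tertile group.

    Mirrors the study's event-count table: one row per weekday (Sunday first)
    plus a Total row; for each of the before/after windows and each of
    {all, morning, evening}, the count of nighttime events and the count of
    those meeting the 4-h retention (columns suffixed ``_4h``).  ``groups``
    maps subject_id to tertile label; when omitted only the ``all`` columns
    are populated.
    """
    night = events[events["is_night"] & events["dst_week"].isin(["before", "after"])]
    if groups is not None:
        glab = night["subject_id"].map(groups)
    else:
        glab = pd.Series(index=night.index, dtype=object)
    retained = (night["retained_duration"] if "retained_duration" in night
                else night["minutes_asleep"] >= 240.0)

    out = pd.DataFrame({"weekday": WEEKDAY_ORDER})
    for window in ("before", "after"):
        in_win = night["dst_week"] == window
        for gname in ("all", "morning", "evening"):
            sel = in_win if gname == "all" else in_win & (glab == gname)
            base = f"{window}_{gname}"
            counts = night.loc[sel, "assigned_weekday"].value_counts()
            kept = night.loc[sel & retained, "assigned_weekday"].value_counts()
            out[base] = [int(counts.get(d, 0)) for d in WEEKDAY_ORDER]
            out[base + "_4h"] = [int(kept.get(d, 0)) for d in WEEKDAY_ORDER]
    return add_totals(out)


def add_totals(counts: pd.DataFrame) -> pd.DataFrame:
    """Append (or refresh) a Total row equal to the per-weekday column sums."""
    body = counts[counts["weekday"] != "Total"]
    total = {"weekday": "Total"}
    for col in body.columns:
        if col != "weekday":
            total[col] = int(body[col].sum())
    return pd.concat([body, pd.DataFrame([total])], ignore_index=True)
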
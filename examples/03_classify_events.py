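"""Classify raw sleep events and build the per-weekday count table.

Nighttime = started 18:00-06:00, attributed to the evening's weekday;
the pre-week runs Saturday March 2 - Friday March 8 2019 and the post-week
Sunday March 10 - Saturday March 16; bouts under four hours asleep are
rejected, and a subject's weekday only counts if observed in both weeks.
"""

from chronodst import (CohortConfig, classify_events, filter_min_duration,
                       generate_cohort, pair_same_weekday, score_cohort,
                       tabulate_counts)

cohort = generate_cohort(CohortConfig(n_subjects=300, seed=3))
classified = pair_same_weekday(filter_min_duration(
    classify_events(cohort.events, CohortConfig().dst_date)))

n_night = int(classified["is_night"].sum())
n_short = int((~classified["retained_duration"]).sum())
n_paired = int(classified["retained_paired"].sum())
print(f"events: {len(classified)} total, {n_night} nighttime, "
      f"{n_short} under 4 h, {n_paired} in the paired analysis set")

result, _ = score_cohort(cohort.genotypes)
counts = tabulate_counts(classified, result.group_map())
print("\nper-weekday nighttime event counts (columns: window_group, "
      "_4h = at least four hours):")
print(counts.to_string(index=False))
# The Total row always equals the column sums — the same arithmetic used on
# the published count table in scripts/acceptance.py.
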
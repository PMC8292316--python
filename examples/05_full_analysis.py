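"""The full pipeline: genotypes + sleep events -> all four result layers.

Runs QC -> PGS -> tertiles -> event classification -> filters -> pairing,
then (1) the per-weekday count table, (2) the before/after asleep-time
t-tests, (3) the daily onset/offset profiles and their shifts, and (4) the
social-jet-lag comparison.
"""

from chronodst import (CohortConfig, RunConfig, generate_cohort,
                       run_full_analysis)

cfg = CohortConfig(n_subjects=250, seed=5)
cohort = generate_cohort(cfg)
bundle = run_full_analysis(cohort.events, cohort.genotypes, RunConfig(seed=5))

print("\n".join(bundle.log_lines))

print("\nasleep-time comparison (work nights, before vs after):")
for group, r in bundle.comparisons["asleep_time"].items():
    b, a = r["group_stats"]["before"], r["group_stats"]["after"]
    print(f"  {group}: {b['mean']:.1f} -> {a['mean']:.1f} min, "
          f"t = {r['statistic']:.2f}, p = {r['p_value']:.3f}")

print("\npre-transition midpoint separation (Watson-Williams):")
for nc, r in bundle.comparisons["midpoint_distribution"].items():
    m = r["group_stats"]["morning"]["mean"]
    e = r["group_stats"]["evening"]["mean"]
    print(f"  {nc} nights: morning {m:.2f}h vs evening {e:.2f}h, "
          f"F = {r['statistic']:.2f}, p = {r['p_value']:.2e}")

print("\nsocial jet lag (free minus work midpoint, minutes):")
for group, r in bundle.comparisons["social_jetlag"].items():
    b, a = r["group_stats"]["before"], r["group_stats"]["after"]
    print(f"  {group}: {b['mean']:.0f} -> {a['mean']:.0f} min, "
          f"t = {r['statistic']:.2f}, p = {r['p_value']:.4f}")

ev = bundle.shifts[bundle.shifts["group"] == "evening"].set_index("weekday")
print(f"\nevening-group Friday onset shift after the transition: "
      f"{ev.loc['Friday', 'shift_onset_min']:.1f} min "
      f"(generator configured 45)")
# An evening-group SJL increase with a stable morning group is the
# signature of a persistently delayed body clock masked by the workweek.
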
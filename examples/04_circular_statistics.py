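"""Circular statistics on time-of-day data.

Clock times live on a 24-h circle (midnight = 0, noon = pi): averaging
23:00 and 01:00 must give midnight, not noon.  The Watson-Williams test
compares circular mean directions between groups.
"""

import numpy as np

from chronodst import (AngleSeries, circular_mean, circular_midpoint,
                       estimate_kappa, hours_to_angle, watson_williams)

naive = np.mean([23.0, 1.0])
circ = circular_mean(AngleSeries.from_hours([23.0, 1.0]))
print(f"mean of 23:00 and 01:00 — linear: {naive:.1f}h (wrong), "
      f"circular: {circ.mean_hours:.1f}h")

mid = circular_midpoint(23.0, 7.0)
print(f"midpoint of a 23:00-07:00 bout: {mid:.1f}h")

summary = circular_mean(AngleSeries.from_hours([22.0, 0.0, 2.0]))
print(f"sample {{22:00, 00:00, 02:00}}: mean {summary.mean_hours:.1f}h, "
      f"resultant length r = {summary.resultant_length:.6f}, "
      f"kappa = {estimate_kappa(summary.resultant_length):.3f}")

# two groups of sleep midpoints 11 minutes apart at cohort-scale n
rng = np.random.default_rng(4)
morning = rng.vonmises(hours_to_angle(3.25), 8.0, size=2700)
evening = rng.vonmises(hours_to_angle(3.25 + 11 / 60), 8.0, size=2700)
res = watson_williams([morning, evening])
print(f"\nWatson-Williams, 11-min separation at n=2700/group: "
      f"F({res.df1},{res.df2}) = {res.f_statistic:.2f}, p = {res.p_value:.2e}")
# r near 1 means tightly clustered times; the correction factor
# 1 + 3/(8 kappa) keeps the F approximation honest at finite concentration.
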
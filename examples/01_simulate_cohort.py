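"""Generate a synthetic study cohort and look at its raw materials.

Builds genotypes with a true additive polygenic signal on sleep midpoint,
latent chronotypes, and two weeks of nightly wearable sleep events around
the March 2019 spring-forward transition, then prints what came out.
"""

from chronodst import CohortConfig, generate_cohort

config = CohortConfig(n_subjects=200, seed=1)
cohort = generate_cohort(config)

print(f"subjects: {config.n_subjects}, variants: {config.n_variants}")
print(f"sleep events generated: {len(cohort.events)} "
      f"(15 nights x {config.n_subjects} subjects, minus missing nights)")
import numpy as np

labels, sizes = np.unique(cohort.true_groups, return_counts=True)
print(f"true tertile sizes: {dict(zip(labels, map(int, sizes)))}")
print("\nfirst three events:")
print(cohort.events.head(3).to_string(index=False))
print(f"\nlatent midpoint range: {cohort.latent_midpoints.min():.2f}h "
      f"to {cohort.latent_midpoints.max():.2f}h "
      f"(population mean {config.baseline_midpoint:.1f}h)")
# Each row is one device-recorded sleep bout in local wall-clock time; the
# latent midpoints are the ground truth the analysis pipeline must recover.
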
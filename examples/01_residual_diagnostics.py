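"""Pearson residuals of pooled mood-pain transitions against the
sticky-uniform null.

Simulates a small cohort whose dynamics are NOT sticky-uniform (one
component is drawn toward the worst state), pools the transition
counts, fits the null model and prints the cells the null fails to
explain.
"""

import numpy as np

from moodpain import fit_null, flag_significant, pearson_residuals, reduced_space
from moodpain.synthetic import CohortSpec, attractor_matrix, simulate_cohort

spec = CohortSpec(
    S=400,
    weights=np.array([0.5, 0.5]),
    matrices=np.stack(
        [attractor_matrix(target=3), attractor_matrix(target=0)]
    ),
    mean_length=40.0,
    seed=1,
)
cohort = simulate_cohort(spec)
Y = cohort.count_array().sum(axis=0)

fit = fit_null(Y)
res = pearson_residuals(Y, fit)
labels = reduced_space().labels

print("pooled transition counts Y:")
print(Y)
print("\nstay probabilities pi_hat:", np.round(fit.pi_hat, 3))
print("\ncells with |R| > 2 (more/fewer transitions than the null expects):")
for i, j, r in flag_significant(res):
    print(f"  {labels[i]} -> {labels[j]}: R = {r:+7.1f}")
print(
    "\nLarge positive residuals mark transitions the sticky-uniform null"
    "\nunderpredicts -- here the pull toward BH and GL that the mixture"
    "\nmodel exists to capture. Diagonal residuals are structurally zero."
)
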
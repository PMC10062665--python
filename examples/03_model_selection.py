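"""Choose the number of clusters by BIC.

Generates a cohort with four well-separated components, scans K = 1..6
with a shared restart policy and prints the negative log-likelihood and
BIC per model.
"""

import numpy as np

from moodpain import model_selection_scan
from moodpain.synthetic import (
    CohortSpec, attractor_matrix, simulate_cohort, sticky_matrix,
)

spec = CohortSpec(
    S=1000,
    weights=np.full(4, 0.25),
    matrices=np.stack(
        [
            attractor_matrix(target=3),
            attractor_matrix(target=0),
            attractor_matrix(target=1),
            sticky_matrix(),
        ]
    ),
    mean_length=40.0,
    seed=17,
)
cohort = simulate_cohort(spec)
table = model_selection_scan(cohort.count_array(), range(1, 7),
                             n_restarts=5, seed=17)

print(" K   negLL      dNegLL     BIC        params")
for K, nll, d, b, p in zip(table.K_values, table.neg_loglik,
                           table.delta_neg_loglik, table.bic, table.n_params):
    d_str = f"{d:9.1f}" if np.isfinite(d) else "        -"
    print(f" {K}   {nll:9.1f} {d_str}  {b:9.1f}   {p}")
print(f"\nBIC minimised at K = {table.best_K()} (the generative truth).")
print(
    "negLL always falls as K grows; BIC penalises the extra parameters"
    "\nand bottoms out at the true number of components."
)
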
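"""Which conditions and pain sites are over-represented in a cluster?

Simulates the paper-like cohort (whose generator links covariate
prevalence to the latent cluster), fits the mixture, hard-assigns
participants and prints log odds ratios with 95% confidence intervals.
"""

import numpy as np
import pandas as pd

from moodpain import assign_clusters, characterise_clusters, fit_em
from moodpain.synthetic import align_components, paper_like_spec, simulate_cohort

spec = paper_like_spec(S=2000, seed=5)
cohort = simulate_cohort(spec)
counts = cohort.count_array()
keep = counts.sum(axis=(1, 2)) > 0
ids = [t.participant_id for t, k in zip(cohort.trajectories, keep) if k]

fit = fit_em(counts[keep], K=4, n_restarts=5, seed=5)

# relabel fitted components to the generator's regime order
perm = align_components(spec.matrices, fit.model.matrices)
inv = np.empty_like(perm)
inv[perm] = np.arange(4)
assignments = pd.Series(inv[assign_clusters(fit.gamma)], index=ids)
regime = ("attract-to-BH", "attract-to-GL", "attract-to-GH", "sticky")

table = characterise_clusters(assignments, cohort.covariates)
strong = table[table["log_or"].abs() > 0.4].dropna()
print("covariate              cluster          logOR   95% CI")
for _, row in strong.iterrows():
    print(
        f"{row['covariate']:22} {regime[row['cluster']]:15} "
        f"{row['log_or']:+6.2f}   ({row['ci_low']:+.2f}, {row['ci_high']:+.2f})"
    )
print(
    "\nPositive logOR: the covariate is more prevalent inside the cluster"
    "\nthan in the pooled remainder. The generator gave fibromyalgia and"
    "\nstomach pain elevated prevalence in the attract-to-GL cluster, and"
    "\nthe fitted clusters recover that link."
)
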
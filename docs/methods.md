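# Methods

## State space and transition counting

Raw diary records carry 1–5 Likert mood and pain scores. The reduced
space dichotomises mood at 3/4 (Bad: 1–3, Good: 4–5) and pain at 2/3
(Low: 1–2, High: 3–5), crossed into four states with the fixed index
order **(GL, GH, BL, BH)**. This order is used for every matrix row and
column in the package; it is a convention, chosen once because source
presentations of the intervention transform are typeset ambiguously,
and documented rather than configurable. The full 25-state space
indexes Likert pairs row-major by mood then pain; the groups have sizes
GL 4, GH 6, BL 6, BH 9 (2×2, 2×3, 3×2, 3×3).

Days missing either score are dropped entirely — only complete
(mood, pain) pairs are analysed; no imputation, and non-response is not
modelled as a state. A participant reporting the same day twice is a
data-integrity error (rejected, not resolved silently). Transitions are
counted between consecutive *reporting* days regardless of the calendar
gap between them, so a trajectory of m observations yields m − 1
counts. Participants with fewer than two observations contribute no
transitions and are excluded from EM fitting with a logged warning.

## Residual diagnostics

The null model is sticky-diagonal with uniform off-diagonal mass: from
state i, stay with probability π̂ᵢ = Yᵢᵢ/N̂ᵢ (N̂ᵢ the row total of the
pooled count matrix Y), otherwise move to each of the n − 1 other
states with probability (1 − π̂ᵢ)/(n − 1). Expected counts are
Eᵢⱼ = N̂ᵢP̂ᵢⱼ and Pearson residuals Rᵢⱼ = (Yᵢⱼ − Eᵢⱼ)/√Eᵢⱼ,
asymptotically standard normal under the null. Two structural facts are
used as self-checks: E row sums equal N̂ᵢ, and diagonal residuals are
exactly zero because π̂ᵢ is estimated from the diagonal itself.

Conventions: rows with zero total get a uniform P̂ row, zero E row, and
a flag; cells with Eᵢⱼ = 0 get residual 0 plus a flag rather than
NaN/∞, keeping downstream summaries total. The normality summary uses
the sample standard deviation (denominator count − 1) and excludes both
flagged cells and the structurally-zero diagonal.

## Mixture of Markov chains and EM

The likelihood conditions on each participant's first observed state:
no initial-state term enters, because the supplementary derivation
specifying one was not available, and the conditional form is the
conservative choice. The component log-likelihood is
Σᵢⱼ Cₛ[i,j]·log M_c[i,j] with the 0·log 0 = 0 convention; a positive
count on a zero probability yields −∞ (a representable sentinel, not an
exception).

- **E-step**: Γ_sc ∝ λ_c exp(L_sc), normalised per participant with
  log-sum-exp. A participant impossible under every component gets
  uniform responsibilities and a warning.
- **M-step**: λ_c is the mean responsibility; M_c row-normalises the
  responsibility-weighted counts with pseudocount ε = 10⁻⁶ per cell.
  The smoothing prevents EM degeneracy (zero probabilities absorbing
  −∞) and guarantees every fitted chain is regular, so stationary
  distributions downstream are unique. Rows with no weighted mass fall
  back to uniform.
- **Initialisation and restarts**: responsibilities drawn from a
  symmetric Dirichlet(1) per participant; default 20 restarts, best
  final log-likelihood wins, ties to the earliest restart; every
  restart is seeded from a single SeedSequence so runs are
  reproducible bit-for-bit.
- **Convergence**: relative log-likelihood change below 10⁻⁸ or 500
  iterations. The EM monotonicity guarantee (log-likelihood
  nondecreasing) is asserted in tests at 10⁻¹⁰ relative tolerance.

Model selection uses BIC = 2·negLL + p·ln(T) with
p = (K − 1) + K·n·(n − 1) free parameters and T the total transition
count across participants. The choice of T as the BIC sample size is a
package decision (the quantity is not defined in the source material)
and is isolated in one function. Hard assignments are argmax
responsibilities, ties to the lowest index.

Clustering defaults to the reduced 4-state space: with 25 states each
component would carry 600 free parameters, and per-participant count
matrices (median ~44 transitions) are far too sparse to estimate them.

## Stationary distributions

A chain is regular iff some power of its matrix is strictly positive;
the test walks the boolean zero-pattern up to the Wielandt bound
(n − 1)² + 1, which is exact for primitivity. The stationary vector
solves (Mᵀ − I)x = 0 with the last equation replaced by Σx = 1, a
deterministic real-arithmetic solve with no eigendecomposition; the
result is validated against ‖xM − x‖∞ ≤ 10⁻¹⁰ and, in tests, against a
200-step power-iteration oracle to 10⁻⁸.

## Intervention transforms

The mood arm rewrites each bad-mood row (BL, BH): destinations GL and
GH each gain β; the leftover bad-mood mass (old BL + old BH − 2β) is
split `split` : (1 − `split`) over BL and BH. The pain arm mirrors this
on high-pain rows (GH, BH), boosting GL and BL and splitting the
leftover over GH and BH. Exactly 2β is added and removed per treated
row, so rows sum to 1 by construction, and untreated rows are
bit-identical.

The default split 0.8 favours the destination that is better on the
*untreated* dimension (BL for the mood arm — low pain; GH for the pain
arm — good mood), matching the beneficial-intervention intent; the
printed description of which destination is disfavoured is
contradictory in the source and the split is configurable so either
reading is runnable. The printed pain-arm formula contains typographic
errors (a mood symbol inside the pain transform, a duplicated 0.8
coefficient, a row that cannot sum to one); the implementation enforces
the symmetric add-and-subtract structure instead.

Feasibility: β is admissible when every transformed entry stays in
[0, 1]; the bound is the minimum over treated rows of
min((reduced-column sum)/2, 1 − each boosted entry), checked per row
with the violating row named in errors. For the uniform matrix the
mood bound is 0.25. The bounds 0.15 (mood) and 0.2 (pain) reported for
the study's fitted matrices require those matrices and are context, not
a reproducible target.

No causal claim attaches to any of this: the transforms are
hypothetical what-ifs on fitted association structure.

## Covariate characterisation

For each (cluster, covariate) pair: a 2×2 table of in-cluster vs
pooled-other-clusters against flag present/absent, participants with
the flag missing excluded. The comparator (pooled others rather than
whole cohort) and the estimator (Wald logOR with ±1.96·SE on the log
scale, Haldane–Anscombe +0.5 on any zero cell, flagged) are package
decisions where the source is silent. A double-zero margin leaves the
estimate undefined and flagged absent. No multiple-testing adjustment
is applied, matching the per-covariate presentation being emulated.

## Synthetic cohort generator

The generator realises the exact generative process the mixture model
assumes, which is what makes recovery tests meaningful: latent cluster
~ mixing weights; daily state evolution by the cluster's chain (initial
state from a supplied distribution, or a 10-step burn-in from uniform
so starts reflect where the chain lives); then imperfect reporting.

- **Span**: 2 + negative binomial with dispersion 3 (configurable);
  the mean is inflated by 1/((1 − gap)(1 − single)) so the *observed*
  complete-pair length averages the target (default 44 days). Only the
  mean length of the emulated study is published; the dispersion and
  gap structure are stand-ins.
- **Thinning**: each day is wholly unreported with probability
  `gap_prob`; surviving days lose one of the two scores with
  probability `single_score_missing` (such days appear in the diary
  export but are dropped from trajectories, exercising the
  complete-pairs rule). Missingness is ignorable by construction —
  state-dependent non-reporting is deliberately not modelled.
- **Covariates**: per-cluster Bernoulli prevalences per flag, with a
  cohort-wide missingness fraction.
- **Paper-like preset**: S = 9990, weights (0.18, 0.16, 0.20, 0.46)
  matching the published cluster shares, and four regime matrices —
  attract-to-BH, attract-to-GL, attract-to-GH (pull 0.55, stay 0.25),
  sticky (diagonal 0.85) — with gap 0.15, single-score 0.05 and
  covariate missingness 0.14 (the emulated study had ~86% of
  participants reporting conditions). The matrices are illustrative
  sketches of the described regimes, not fitted values: the study's
  diaries are not publicly deposited, so fitted-matrix, stationary and
  intervention-delta values from the study are *not* reproduction
  targets anywhere in this package.

What passing tests show, and what they do not: recovery and
model-selection results demonstrate correctness of the estimator under
its own assumptions (Markov dynamics, ignorable missingness, exact
cluster structure). Real diaries violate these in unknown ways —
non-Markov dependence, informative missingness, state spaces that are
only approximately homogeneous within clusters — so test performance
bounds what the method can do on clean data, not what it did on the
study's data.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 200–9990 participants with
mean lengths 10–50 days, 5–10 EM restarts, and 1000-matrix sweeps for
the stationary and intervention property checks; these sizes give
stable statistics while keeping the full suite fast. Tolerances: row
simplex checks at 10⁻⁹; stationary residual 10⁻¹⁰ (solve) / 10⁻⁹
(property) / 10⁻⁸ (vs power iteration); EM monotonicity 10⁻¹⁰
relative; intervention row sums 10⁻¹² (construction-exact up to float
rounding). Ties everywhere break toward the lowest index and are
deterministic.

## Known limitations

- Conditional likelihood (no initial-state term); adding one is a
  localised change in `component_loglik`/`m_step`.
- Hard assignments feed the covariate analysis; a
  responsibility-weighted variant is out of scope.
- No hidden-Markov measurement noise, no relaxation of the Markov
  assumption, no weather covariates, no causal inference.
- The BIC sample-size convention (total transitions) is one of several
  defensible choices and is configurable at the call site.
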
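"""Hypothetical mood- and pain-improving transition-matrix transforms.

An intervention is modelled as a deterministic rewrite of a cluster's
transition matrix.  The mood arm boosts, in every row starting from a
bad-mood state (BL, BH), the probabilities of moving to the good-mood
destinations (GL, GH) by beta each; the 2 * beta removed is taken from
the bad-mood destinations, whose leftover mass (old BL + old BH -
2 beta) is redistributed with a configurable split (default 0.8 to BL,
the destination with low pain, and 0.2 to BH).  Rows starting from
good-mood states are untouched.  The pain arm mirrors this: rows from
high-pain states (GH, BH) get + beta on the low-pain destinations (GL,
BL), with the leftover split 0.8 to GH and 0.2 to BH.

Because exactly 2 * beta is added and removed per treated row, rows sum
to 1 identically; beta is feasible as long as every entry stays in
[0, 1], which :func:`max_feasible_beta` computes per matrix.  The effect
of an intervention on a cluster is summarised by the change in its
stationary distribution.

State indices follow the canonical (GL, GH, BL, BH) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import stationary
from .mixture import MixtureModel

__all__ = [
    "InterventionSpec",
    "InterventionResult",
    "apply_mood_intervention",
    "apply_pain_intervention",
    "apply_intervention",
    "max_feasible_beta",
    "intervention_report",
]

GL, GH, BL, BH = 0, 1, 2, 3

# (boosted destination columns, reduced destination columns, treated rows)
# reduced columns ordered (preferred, other): the split fraction goes to
# the destination that is better on the untreated dimension.
_ARMS = {
    "mood": {"rows": (BL, BH), "boost": (GL, GH), "reduce": (BL, BH)},
    "pain": {"rows": (GH, BH), "boost": (GL, BL), "reduce": (GH, BH)},
}


@dataclass(frozen=True)
class InterventionSpec:
    """Which dimension is treated, the boost beta, and the leftover split.

    ``split`` is the fraction of leftover mass sent to the preferred
    non-improved destination (BL for the mood arm, GH for the pain arm).
    """

    target: str          # "mood" or "pain"
    beta: float
    split: float = 0.8

    def __post_init__(self) -> None:
        if self.target not in _ARMS:
            raise ValueError("target must be 'mood' or 'pain'")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if not 0.0 <= self.split <= 1.0:
            raise ValueError("split must be in [0, 1]")


@dataclass(frozen=True)
class InterventionResult:
    """Transformed matrix with before/after stationary distributions."""

    M_prime: np.ndarray
    x_before: np.ndarray
    x_after: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.x_after - self.x_before


def _check_matrix(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError("intervention transforms apply to 4x4 reduced-state matrices")
    if np.any(M < -1e-9) or np.max(np.abs(M.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("matrix is not row-stochastic")
    return M


def apply_intervention(M: np.ndarray, spec: InterventionSpec) -> np.ndarray:
    """Apply the spec's transform, erroring if beta is infeasible."""
    M = _check_matrix(M)
    arm = _ARMS[spec.target]
    beta, split = spec.beta, spec.split
    out = M.copy()
    for i in arm["rows"]:
        leftover = M[i, arm["reduce"][0]] + M[i, arm["reduce"][1]] - 2.0 * beta
        if leftover < -1e-12:
            raise ValueError(
                f"beta={beta} infeasible: row {i} has only "
                f"{leftover + 2 * beta:.4f} mass on the reduced destinations"
            )
        for j in arm["boost"]:
            if M[i, j] + beta > 1.0 + 1e-12:
                raise ValueError(
                    f"beta={beta} infeasible: entry ({i}, {j}) would exceed 1"
                )
            out[i, j] = M[i, j] + beta
        leftover = max(leftover, 0.0)
        out[i, arm["reduce"][0]] = split * leftover
        out[i, arm["reduce"][1]] = (1.0 - split) * leftover
    return out


def apply_mood_intervention(M: np.ndarray, spec: InterventionSpec) -> np.ndarray:
    """Boost bad-mood -> good-mood transitions by ``spec.beta``."""
    if spec.target != "mood":
        raise ValueError("spec.target must be 'mood'")
    return apply_intervention(M, spec)


def apply_pain_intervention(M: np.ndarray, spec: InterventionSpec) -> np.ndarray:
    """Boost high-pain -> low-pain transitions by ``spec.beta``."""
    if spec.target != "pain":
        raise ValueError("spec.target must be 'pain'")
    return apply_intervention(M, spec)


def max_feasible_beta(M: np.ndarray, target: str) -> float:
    """Largest beta keeping every transformed entry in [0, 1].

    Per treated row the binding constraints are: the leftover mass on
    the two reduced destinations stays nonnegative (beta <= their sum
    over 2), and each boosted entry stays at most 1 (beta <= 1 - entry).
    """
    M = _check_matrix(M)
    arm = _ARMS[target] if target in _ARMS else None
    if arm is None:
        raise ValueError("target must be 'mood' or 'pain'")
    bound = np.inf
    for i in arm["rows"]:
        bound = min(bound, (M[i, arm["reduce"][0]] + M[i, arm["reduce"][1]]) / 2.0)
        for j in arm["boost"]:
            bound = min(bound, 1.0 - M[i, j])
    return max(float(bound), 0.0)


def intervention_report(
    model: MixtureModel, spec: InterventionSpec
) -> list[InterventionResult]:
    """Before/after stationary distributions for every cluster.

    Requires every cluster's chain to be regular both before and after
    the transform (smoothed EM fits always are).
    """
    results = []
    for M in model.matrices:
        M_prime = apply_intervention(M, spec)
        results.append(
            InterventionResult(
                M_prime=M_prime,
                x_before=stationary(M),
                x_after=stationary(M_prime),
            )
        )
    return results
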
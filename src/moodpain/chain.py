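"""Stationary distributions of fitted per-cluster transition matrices.

A regular (primitive) chain -- one for which some power of the
transition matrix is strictly positive -- has a unique stationary
distribution x solving x M = x with x on the probability simplex.  For
an ergodic chain, x_k is the long-run fraction of time a participant
spends in state k, which is how per-cluster occupancy is summarised.

The solver replaces one equation of the singular system (M^T - I) x = 0
with the normalisation sum(x) = 1 and solves the resulting square
system directly: deterministic, real arithmetic, no eigendecomposition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixture import MixtureModel

__all__ = ["is_regular", "stationary", "occupancy_report"]


def _check_row_stochastic(M: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(M < -tol) or np.max(np.abs(M.sum(axis=1) - 1.0)) > tol:
        raise ValueError("matrix is not row-stochastic")
    return M


def is_regular(M: np.ndarray, max_power: int | None = None) -> bool:
    """Whether some power M^m (m <= max_power) is strictly positive.

    The default bound (n-1)^2 + 1 is the Wielandt primitivity bound: a
    primitive n-state chain must have an all-positive power by then.
    Works on the zero-pattern with boolean products, so no underflow.
    """
    M = _check_row_stochastic(M)
    n = M.shape[0]
    if max_power is None:
        max_power = (n - 1) ** 2 + 1
    A = M > 0
    power = A.copy()
    for _ in range(max_power):
        if power.all():
            return True
        power = (power @ A) > 0
    return bool(power.all())


def stationary(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unique stationary distribution of a regular chain.

    Solves (M^T - I) x = 0 with the last equation replaced by
    sum(x) = 1.  Raises if the chain is not regular (the distribution
    would not be unique) or if the residual ||xM - x|| exceeds ``tol``.
    """
    M = _check_row_stochastic(M)
    if not is_regular(M):
        raise ValueError(
            "chain is not regular; the stationary distribution is not unique"
        )
    n = M.shape[0]
    A = M.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    x = np.linalg.solve(A, b)
    x = np.clip(x, 0.0, None)
    x /= x.sum()
    residual = np.max(np.abs(x @ M - x))
    if residual > tol:
        raise ArithmeticError(f"stationary solve residual {residual:.3e} > {tol:.1e}")
    return x


def occupancy_report(model: MixtureModel, labels=None) -> pd.DataFrame:
    """Per-cluster stationary distributions as a K x n table.

    Row k gives the modelled long-run fraction of time a participant in
    cluster k spends in each state.
    """
    rows = [stationary(M) for M in model.matrices]
    if labels is None:
        labels = [f"state_{j}" for j in range(model.n_states)]
    return pd.DataFrame(
        rows,
        index=[f"cluster_{k + 1}" for k in range(model.K)],
        columns=list(labels),
    )
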
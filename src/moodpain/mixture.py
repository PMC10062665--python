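"""Mixture-of-Markov-chains clustering of per-participant transition counts.

Each participant s contributes an n x n matrix C_s of transition counts
between consecutive reporting days.  The model assumes s was drawn from
one of K latent components, component c having mixing weight lambda_c
and its own row-stochastic transition matrix M_c.  Conditional on the
first observed state, the log-likelihood of participant s under
component c is

    L_sc = sum_ij C_s[i, j] * log M_c[i, j],

and the marginal log-likelihood is sum_s log sum_c lambda_c exp(L_sc).
Parameters are estimated by EM: the E-step computes responsibilities
Gamma_sc (posterior component membership) by log-sum-exp, and the M-step
re-estimates weights as mean responsibilities and each M_c as the
responsibility-weighted transition counts, row-normalised with a small
pseudocount so every probability stays positive (which also keeps the
fitted chains regular).  The number of components is chosen by BIC over
a range of K.

Counts are passed as a single (S, n, n) array throughout; the helpers in
:mod:`moodpain.state_space` build it from diary records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MixtureModel",
    "FitResult",
    "ModelSelectionTable",
    "component_loglik",
    "e_step",
    "m_step",
    "fit_em",
    "assign_clusters",
    "model_selection_scan",
    "bic",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class MixtureModel:
    """K mixing weights and K row-stochastic transition matrices."""

    weights: np.ndarray   # (K,), simplex
    matrices: np.ndarray  # (K, n, n), each row-stochastic

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        M = np.asarray(self.matrices, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "matrices", M)
        if w.ndim != 1 or M.ndim != 3 or M.shape[0] != w.size:
            raise ValueError("weights must be (K,) and matrices (K, n, n)")
        if M.shape[1] != M.shape[2]:
            raise ValueError("transition matrices must be square")
        if np.any(w < -_ROW_TOL) or abs(w.sum() - 1.0) > _ROW_TOL:
            raise ValueError("mixing weights must lie on the simplex")
        if np.any(M < -_ROW_TOL) or np.any(M > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must be in [0, 1]")
        if np.max(np.abs(M.sum(axis=2) - 1.0)) > _ROW_TOL:
            raise ValueError("each transition-matrix row must sum to 1")

    @property
    def K(self) -> int:
        return int(self.weights.size)

    @property
    def n_states(self) -> int:
        return int(self.matrices.shape[1])


@dataclass(frozen=True)
class FitResult:
    """Outcome of one EM fit (best of the requested restarts)."""

    model: MixtureModel
    gamma: np.ndarray           # (S, K) responsibilities
    log_likelihood: float
    loglik_trace: np.ndarray    # per-iteration total log-likelihood
    n_iter: int
    converged: bool
    seed: int


@dataclass(frozen=True)
class ModelSelectionTable:
    """Per-K fit summaries for choosing the number of components."""

    K_values: np.ndarray
    neg_loglik: np.ndarray
    delta_neg_loglik: np.ndarray  # negLL(K-1) - negLL(K); NaN for first row
    bic: np.ndarray
    n_params: np.ndarray
    fits: tuple[FitResult, ...]

    def best_K(self) -> int:
        return int(self.K_values[np.argmin(self.bic)])


def _as_count_array(counts) -> np.ndarray:
    C = np.asarray(counts, dtype=float)
    if C.ndim == 2:
        C = C[None]
    if C.ndim != 3 or C.shape[1] != C.shape[2]:
        raise ValueError("counts must be an (S, n, n) array of matrices")
    if np.any(C < 0):
        raise ValueError("transition counts must be nonnegative")
    return C


def component_loglik(counts, matrices) -> np.ndarray:
    """Log-likelihood of each participant's counts under each chain.

    Returns an (S, K) array of sum_ij C_s[i,j] log M_c[i,j].  Zero counts
    contribute nothing even where M is zero; a positive count on a zero
    probability yields -inf for that (participant, component) pair.
    """
    C = _as_count_array(counts)
    M = np.asarray(matrices, dtype=float)
    if M.ndim == 2:
        M = M[None]
    S, n = C.shape[0], C.shape[1]
    with np.errstate(divide="ignore"):
        logM = np.log(M)
    # 0 * log 0 -> 0 by convention; only C > 0 cells may emit -inf
    flatC = C.reshape(S, n * n)
    flatL = logM.reshape(M.shape[0], n * n)
    safe = np.where(np.isneginf(flatL), 0.0, flatL)
    ll = flatC @ safe.T
    impossible = (flatC > 0) @ np.isneginf(flatL).T.astype(float)
    ll[impossible > 0] = -np.inf
    return ll


def e_step(model: MixtureModel, counts) -> tuple[np.ndarray, float]:
    """Posterior responsibilities and total log-likelihood.

    Gamma_sc is proportional to lambda_c * exp(L_sc), normalised per
    participant in the log domain.  A participant impossible under every
    component (all -inf) gets uniform responsibilities.
    """
    ll = component_loglik(counts, model.matrices)
    with np.errstate(divide="ignore"):
        joint = ll + np.log(model.weights)[None, :]
    norm = logsumexp(joint, axis=1)
    degenerate = np.isneginf(norm)
    with np.errstate(invalid="ignore"):
        gamma = np.exp(joint - norm[:, None])
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} participant(s) impossible under every "
            "component; responsibilities set uniform",
            RuntimeWarning,
            stacklevel=2,
        )
        gamma[degenerate] = 1.0 / model.K
        return gamma, -np.inf
    return gamma, float(norm.sum())


def m_step(gamma: np.ndarray, counts, smoothing: float = 1e-6) -> MixtureModel:
    """Re-estimate weights and transition matrices from responsibilities.

    M_c[i, j] = (sum_s Gamma_sc C_s[i, j] + eps) /
                (sum_s Gamma_sc sum_k C_s[i, k] + n * eps)

    The pseudocount eps keeps all probabilities positive; rows with no
    weighted mass at all fall back to uniform.
    """
    C = _as_count_array(counts)
    gamma = np.asarray(gamma, dtype=float)
    S, n = C.shape[0], C.shape[1]
    if gamma.shape[0] != S:
        raise ValueError("gamma rows must match the number of participants")
    weights = gamma.mean(axis=0)
    weights = weights / weights.sum()
    # (K, n, n) responsibility-weighted counts
    wc = np.einsum("sk,sij->kij", gamma, C)
    num = wc + smoothing
    den = wc.sum(axis=2, keepdims=True) + n * smoothing
    with np.errstate(invalid="ignore"):
        matrices = np.where(den > 0, num / np.where(den == 0, 1.0, den), 1.0 / n)
    return MixtureModel(weights=weights, matrices=matrices)


def _init_gamma(rng: np.random.Generator, S: int, K: int) -> np.ndarray:
    # symmetric Dirichlet(1) responsibilities per participant
    g = rng.dirichlet(np.ones(K), size=S)
    return g


def _single_em_run(
    C: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    smoothing: float,
) -> tuple[MixtureModel, np.ndarray, list[float], bool]:
    S = C.shape[0]
    gamma = _init_gamma(rng, S, K)
    model = m_step(gamma, C, smoothing)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        gamma, ll = e_step(model, C)
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            rel = abs(ll - prev) / max(1.0, abs(prev))
            if rel < tol:
                converged = True
                break
        model = m_step(gamma, C, smoothing)
    return model, gamma, trace, converged


def fit_em(
    counts,
    K: int,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    smoothing: float = 1e-6,
) -> FitResult:
    """Fit a K-component mixture by EM, best of ``n_restarts`` starts.

    Each restart draws initial responsibilities from a symmetric
    Dirichlet(1); the run with the highest final log-likelihood wins
    (ties resolved in favour of the earliest restart).  Convergence is
    declared when the relative log-likelihood change drops below
    ``tol``.  Fully reproducible for a given ``seed``.
    """
    C = _as_count_array(counts)
    S = C.shape[0]
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > S:
        raise ValueError(f"cannot fit K={K} components to {S} participants")
    if not np.any(C.sum(axis=(1, 2)) > 0):
        raise ValueError("need at least one participant with a transition")

    best: FitResult | None = None
    root = np.random.SeedSequence(seed)
    for restart, child in enumerate(root.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        model, gamma, trace, converged = _single_em_run(
            C, K, rng, max_iter, tol, smoothing
        )
        result = FitResult(
            model=model,
            gamma=gamma,
            log_likelihood=trace[-1],
            loglik_trace=np.asarray(trace),
            n_iter=len(trace),
            converged=converged,
            seed=seed,
        )
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


def assign_clusters(gamma: np.ndarray) -> np.ndarray:
    """Hard cluster assignment: argmax responsibility per participant.

    Ties go to the lowest component index (numpy argmax convention).
    """
    gamma = np.asarray(gamma, dtype=float)
    return np.argmax(gamma, axis=1)


def n_free_parameters(K: int, n: int) -> int:
    """Free parameters: K - 1 mixing weights plus K matrices of n rows
    with n - 1 free entries each."""
    return (K - 1) + K * n * (n - 1)


def bic(neg_loglik: float, K: int, n: int, total_transitions: int) -> float:
    """BIC = 2 negLL + p ln(T) with T the total transition count."""
    p = n_free_parameters(K, n)
    return 2.0 * neg_loglik + p * math.log(total_transitions)


def model_selection_scan(
    counts,
    K_range,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    smoothing: float = 1e-6,
) -> ModelSelectionTable:
    """Fit the mixture for each K and tabulate negLL, delta-negLL and BIC.

    All K share the same restart policy and base seed.  The BIC sample
    size is the total number of observed transitions across
    participants.
    """
    K_values = sorted(set(int(k) for k in K_range))
    if not K_values:
        raise ValueError("K_range must be nonempty")
    C = _as_count_array(counts)
    n = C.shape[1]
    T = int(C.sum())
    fits = []
    negll = []
    bics = []
    params = []
    for K in K_values:
        fit = fit_em(
            C, K, n_restarts=n_restarts, max_iter=max_iter,
            tol=tol, seed=seed, smoothing=smoothing,
        )
        fits.append(fit)
        nll = -fit.log_likelihood
        negll.append(nll)
        bics.append(bic(nll, K, n, T))
        params.append(n_free_parameters(K, n))
    negll_arr = np.asarray(negll)
    delta = np.full(len(K_values), np.nan)
    delta[1:] = negll_arr[:-1] - negll_arr[1:]
    return ModelSelectionTable(
        K_values=np.asarray(K_values),
        neg_loglik=negll_arr,
        delta_neg_loglik=delta,
        bic=np.asarray(bics),
        n_params=np.asarray(params),
        fits=tuple(fits),
    )
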
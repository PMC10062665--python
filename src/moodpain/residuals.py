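"""Pearson residual diagnostics for pooled transition counts.

The null model is "sticky diagonal + uniform off-diagonal": from state i
a participant stays with probability pi_i and otherwise moves to each of
the n - 1 other states with equal probability.  Fitting by maximum
likelihood gives, for pooled counts Y,

    N_i  = sum_k Y_ik          (row totals)
    pi_i = Y_ii / N_i          (stay probability)
    P_ij = pi_i on the diagonal, (1 - pi_i)/(n - 1) off it
    E_ij = N_i * P_ij          (expected counts)

and the Pearson residuals R_ij = (Y_ij - E_ij)/sqrt(E_ij), which are
asymptotically standard normal when the null holds.  Large |R| flags
transitions observed much more (or less) often than the sticky-uniform
null predicts.  Note the diagonal residuals are structurally zero:
E_ii = Y_ii by construction of pi_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NullModelFit",
    "ResidualMatrix",
    "fit_null",
    "pearson_residuals",
    "flag_significant",
    "residual_normality_summary",
]


@dataclass(frozen=True)
class NullModelFit:
    """MLE fit of the sticky-uniform null to a pooled count matrix."""

    N_hat: np.ndarray        # row totals
    pi_hat: np.ndarray       # stay probabilities (NaN on empty rows)
    P_hat: np.ndarray        # null transition probabilities, row-stochastic
    E: np.ndarray            # expected counts, row sums equal N_hat
    empty_rows: np.ndarray   # boolean mask of rows with zero total


@dataclass(frozen=True)
class ResidualMatrix:
    """Pearson residuals with a mask of cells where E was zero."""

    R: np.ndarray
    zero_expected: np.ndarray  # boolean mask; residual set to 0 there


def fit_null(Y: np.ndarray) -> NullModelFit:
    """Fit the sticky-diagonal / uniform-off-diagonal null by MLE.

    Rows with zero total have no stay-probability estimate; by
    convention their P row is uniform, their E row zero, and the row is
    flagged in ``empty_rows``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != Y.shape[1]:
        raise ValueError("Y must be a square matrix")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 states")
    if np.any(Y < 0):
        raise ValueError("counts must be nonnegative")

    N_hat = Y.sum(axis=1)
    empty = N_hat == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_hat = np.where(empty, np.nan, np.diag(Y) / np.where(empty, 1.0, N_hat))

    off = (1.0 - np.where(empty, np.nan, pi_hat)) / (n - 1)
    P_hat = np.repeat(off[:, None], n, axis=1)
    np.fill_diagonal(P_hat, pi_hat)
    P_hat[empty] = 1.0 / n  # flagged convention for uninformative rows

    E = N_hat[:, None] * P_hat
    E[empty] = 0.0
    return NullModelFit(N_hat=N_hat, pi_hat=pi_hat, P_hat=P_hat, E=E, empty_rows=empty)


def pearson_residuals(Y: np.ndarray, fit: NullModelFit) -> ResidualMatrix:
    """Compute R_ij = (Y_ij - E_ij) / sqrt(E_ij) against a null fit.

    Cells with E_ij = 0 get residual 0 and are flagged rather than
    producing NaN/inf, so downstream summaries stay total.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape != fit.E.shape:
        raise ValueError("Y and fitted E have different shapes")
    zero_expected = fit.E == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Y - fit.E) / np.sqrt(fit.E)
    R[zero_expected] = 0.0
    return ResidualMatrix(R=R, zero_expected=zero_expected)


def flag_significant(
    res: ResidualMatrix, threshold: float = 2.0
) -> list[tuple[int, int, float]]:
    """Cells with |R| above the threshold, sorted by |R| descending.

    The conventional cut-off of 2 corresponds to roughly two standard
    normal deviations; ties are broken by row-major cell order.
    """
    R = res.R
    ii, jj = np.nonzero(np.abs(R) > threshold)
    cells = [(int(i), int(j), float(R[i, j])) for i, j in zip(ii, jj)]
    cells.sort(key=lambda c: (-abs(c[2]), c[0], c[1]))
    return cells


def residual_normality_summary(
    res: ResidualMatrix, bins: int = 20, exclude_diagonal: bool = True
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Mean, sample SD and histogram of the informative residuals.

    Diagonal cells (structurally zero under this null) and cells with
    zero expected count are excluded.  Returns ``(mean, sd, hist_counts,
    bin_edges)``; SD uses denominator (count - 1).
    """
    mask = ~res.zero_expected
    if exclude_diagonal:
        mask = mask & ~np.eye(res.R.shape[0], dtype=bool)
    values = res.R[mask]
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 informative residual cells")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    hist, edges = np.histogram(values, bins=bins)
    return mean, sd, hist, edges
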
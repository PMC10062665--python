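"""Association of cluster membership with binary covariates.

Participants self-report chronic pain conditions (rheumatoid arthritis,
fibromyalgia, ...) and sites of pain (back, knee, ...) as binary flags,
possibly missing.  For each (cluster, covariate) pair a 2x2 table is
built from hard cluster assignments -- participants in the cluster vs
all other clusters pooled, covariate present vs absent, missing
excluded -- and summarised by the log odds ratio with a 95% Wald
confidence interval on the log scale.  Tables containing a zero cell
get the Haldane-Anscombe +0.5 correction (flagged in the result); a
double zero in a row or column leaves the estimate undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LogOddsResult", "contingency", "log_odds_ratio", "characterise_clusters"]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class LogOddsResult:
    """Log odds ratio of a covariate in one cluster vs the others."""

    covariate: str
    cluster: int
    log_or: float | None
    ci_low: float | None
    ci_high: float | None
    table: tuple[float, float, float, float]  # (a, b, c, d)
    corrected: bool  # Haldane-Anscombe +0.5 applied
    n: int           # participants with the covariate observed


def contingency(
    assignments: pd.Series | dict,
    covariate: pd.Series | dict,
    cluster: int,
) -> tuple[int, int, int, int]:
    """2x2 table (a, b, c, d) for one cluster and one binary covariate.

    a = in-cluster with the covariate, b = in-cluster without,
    c = out-of-cluster with, d = out-of-cluster without.  Participants
    with the covariate missing are excluded; only participants present
    in both inputs contribute.
    """
    assign = pd.Series(assignments)
    cov = pd.Series(covariate)
    joined = pd.concat({"cluster": assign, "flag": cov}, axis=1, join="inner")
    joined = joined.dropna(subset=["flag"])
    if not (assign == cluster).any():
        raise ValueError(f"cluster {cluster} has no members")
    in_cluster = joined["cluster"] == cluster
    flag = joined["flag"].astype(float) > 0
    a = int((in_cluster & flag).sum())
    b = int((in_cluster & ~flag).sum())
    c = int((~in_cluster & flag).sum())
    d = int((~in_cluster & ~flag).sum())
    return a, b, c, d


def log_odds_ratio(
    table: tuple[float, float, float, float],
    covariate: str = "",
    cluster: int = -1,
) -> LogOddsResult:
    """Wald log odds ratio with 95% CI for a 2x2 table.

    logOR = log(ad / bc), SE = sqrt(1/a + 1/b + 1/c + 1/d).  If any cell
    is zero, 0.5 is added to all four cells first (Haldane-Anscombe) and
    the result is flagged.  If both cells of a row or column are zero
    the odds ratio is undefined and the estimate is returned absent.
    """
    a, b, c, d = (float(v) for v in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be nonnegative")
    n = int(a + b + c + d)
    undefined = (a == 0 and b == 0) or (c == 0 and d == 0) \
        or (a == 0 and c == 0) or (b == 0 and d == 0)
    if undefined:
        return LogOddsResult(covariate, cluster, None, None, None,
                             (a, b, c, d), corrected=False, n=n)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return LogOddsResult(
        covariate, cluster,
        log_or, log_or - _Z95 * se, log_or + _Z95 * se,
        (a, b, c, d), corrected=corrected, n=n,
    )


def characterise_clusters(
    assignments: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Log odds ratios of every covariate in every cluster.

    ``assignments`` maps participant id to hard cluster index;
    ``covariates`` is a participant-indexed frame of binary flags with
    NaN for not reported.  Returns a tidy frame with one row per
    (covariate, cluster).
    """
    rows = []
    clusters = sorted(pd.Series(assignments).unique())
    for name in covariates.columns:
        for k in clusters:
            tab = contingency(assignments, covariates[name], k)
            res = log_odds_ratio(tab, covariate=name, cluster=int(k))
            rows.append(
                {
                    "covariate": name,
                    "cluster": int(k),
                    "log_or": res.log_or,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "a": res.table[0], "b": res.table[1],
                    "c": res.table[2], "d": res.table[3],
                    "corrected": res.corrected,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
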
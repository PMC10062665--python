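"""Serialisation of fitted models and tidy tables.

Models go to JSON (language-neutral, diff-able); tabular outputs are
tidy CSV throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mixture import FitResult, MixtureModel
from .residuals import NullModelFit, ResidualMatrix

__all__ = [
    "save_model",
    "load_model",
    "assignments_frame",
    "residuals_frame",
    "counts_to_json",
]


def save_model(
    fit: FitResult,
    path,
    state_labels=None,
    settings: dict | None = None,
) -> None:
    """Write a fitted mixture to JSON.

    Schema: ``{K, weights, matrices, state_labels, loglik, seed,
    n_iter, converged, settings}``.
    """
    model = fit.model
    payload = {
        "K": model.K,
        "weights": model.weights.tolist(),
        "matrices": model.matrices.tolist(),
        "state_labels": list(state_labels) if state_labels is not None else None,
        "loglik": fit.log_likelihood,
        "seed": fit.seed,
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "settings": settings or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> tuple[MixtureModel, dict]:
    """Read a model JSON back; returns the model and the full payload."""
    payload = json.loads(Path(path).read_text())
    model = MixtureModel(
        weights=np.asarray(payload["weights"]),
        matrices=np.asarray(payload["matrices"]),
    )
    return model, payload


def assignments_frame(participant_ids, gamma: np.ndarray) -> pd.DataFrame:
    """Tidy frame of hard assignments and responsibilities per participant."""
    gamma = np.asarray(gamma)
    data = {"participant_id": list(participant_ids)}
    data["cluster"] = np.argmax(gamma, axis=1) + 1
    for k in range(gamma.shape[1]):
        data[f"gamma_{k + 1}"] = gamma[:, k]
    return pd.DataFrame(data)


def residuals_frame(
    Y: np.ndarray, fit: NullModelFit, res: ResidualMatrix, labels=None
) -> pd.DataFrame:
    """Tidy (from, to, Y, E, R) table of observed, expected and residual."""
    n = fit.E.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return pd.DataFrame(
        {
            "from": [labels[i] for i in ii.ravel()],
            "to": [labels[j] for j in jj.ravel()],
            "Y": np.asarray(Y, dtype=float).ravel(),
            "E": fit.E.ravel(),
            "R": res.R.ravel(),
            "zero_expected": res.zero_expected.ravel(),
        }
    )


def counts_to_json(counts_by_participant: dict, path) -> None:
    """Write per-participant count matrices keyed by id (row-major lists)."""
    payload = {
        str(pid): np.asarray(C, dtype=int).tolist()
        for pid, C in counts_by_participant.items()
    }
    Path(path).write_text(json.dumps(payload))
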
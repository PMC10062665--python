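"""End-to-end orchestration of the mood-pain trajectory analysis.

One call runs the requested stages in dependency order -- simulate or
ingest a diary, count transitions, residual diagnostics, EM fit (or a
K-scan), stationary distributions, intervention what-ifs, covariate
characterisation -- writing tidy CSV tables, a model JSON and a run
manifest (seeds, settings, stage status, file checksums) so any output
is regenerable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterise import characterise_clusters
from .chain import occupancy_report
from .intervention import InterventionSpec, intervention_report
from .io import assignments_frame, residuals_frame, save_model
from .mixture import assign_clusters, fit_em, model_selection_scan
from .residuals import fit_null, pearson_residuals
from .state_space import full_space, read_diary_csv, reduced_space
from .synthetic import paper_like_spec, simulate_cohort, transition_count_array

logger = logging.getLogger("moodpain")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    out_dir: str
    diary_csv: str | None = None          # ingest this file ...
    simulate: bool = False                # ... or simulate the paper-like preset
    simulate_size: int = 9990
    space: str = "reduced"                # state space for residual diagnostics
    K: int | None = 4
    K_range: tuple[int, ...] | None = None
    n_restarts: int = 20
    seed: int = 0
    betas: tuple[float, float] = (0.15, 0.15)  # (mood, pain)
    split: float = 0.8
    residual_threshold: float = 2.0
    covariates_csv: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        if cfg.K_range is not None:
            cfg.K_range = tuple(int(k) for k in cfg.K_range)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "stages": {},
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    def finish(status: str, failed_stage: str | None = None) -> dict:
        manifest["status"] = status
        if failed_stage:
            manifest["failed_stage"] = failed_stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    stage = "ingest"
    try:
        # --- ingest or simulate -------------------------------------------
        covariates = None
        truth = None
        if config.simulate:
            stage = "simulate"
            spec = paper_like_spec(S=config.simulate_size, seed=config.seed)
            cohort = simulate_cohort(spec)
            trajectories = cohort.trajectories
            covariates = cohort.covariates
            truth = cohort.labels
            diary_path = out / "diary.csv"
            cohort.diary.to_csv(diary_path, index=False)
            record("diary", diary_path)
            truth_path = out / "truth.csv"
            pd.DataFrame(
                {
                    "participant_id": [t.participant_id for t in trajectories],
                    "true_cluster": truth + 1,
                }
            ).to_csv(truth_path, index=False)
            record("truth", truth_path)
        elif config.diary_csv:
            if not Path(config.diary_csv).exists():
                raise FileNotFoundError(f"diary file not found: {config.diary_csv}")
            trajectories = read_diary_csv(config.diary_csv, reduced_space())
        else:
            raise ValueError("config must set either diary_csv or simulate")
        manifest["stages"]["ingest"] = "ok"

        # --- residual diagnostics -----------------------------------------
        stage = "residuals"
        space = full_space() if config.space == "full" else reduced_space()
        if config.space == "full" and config.diary_csv:
            res_trajs = read_diary_csv(config.diary_csv, space)
        elif config.space == "full":
            res_trajs = None  # simulated cohorts are reduced-state
            logger.info("skipping full-space residuals for a simulated cohort")
        else:
            res_trajs = trajectories
        if res_trajs is not None:
            Y = transition_count_array(res_trajs).sum(axis=0)
            null_fit = fit_null(Y)
            res = pearson_residuals(Y, null_fit)
            res_path = out / "residuals.csv"
            residuals_frame(Y, null_fit, res, labels=space.labels).to_csv(
                res_path, index=False
            )
            record("residuals", res_path)
        manifest["stages"]["residuals"] = "ok"

        # --- transition counts and EM fit ---------------------------------
        stage = "fit"
        counts = transition_count_array(trajectories)
        informative = counts.sum(axis=(1, 2)) > 0
        n_dropped = int((~informative).sum())
        if n_dropped:
            logger.warning(
                "%d participants with < 2 observations excluded from EM", n_dropped
            )
        fit_counts = counts[informative]
        kept_ids = [
            t.participant_id for t, keep in zip(trajectories, informative) if keep
        ]

        if config.K_range:
            stage = "select-k"
            table = model_selection_scan(
                fit_counts, config.K_range,
                n_restarts=config.n_restarts, seed=config.seed,
            )
            scan_path = out / "model_selection.csv"
            pd.DataFrame(
                {
                    "K": table.K_values,
                    "neg_loglik": table.neg_loglik,
                    "delta_neg_loglik": table.delta_neg_loglik,
                    "BIC": table.bic,
                    "n_params": table.n_params,
                }
            ).to_csv(scan_path, index=False)
            record("model_selection", scan_path)
            best_K = table.best_K()
            fit = table.fits[int(np.argmin(table.bic))]
            manifest["stages"]["select-k"] = f"best K = {best_K}"
        else:
            fit = fit_em(
                fit_counts, config.K,
                n_restarts=config.n_restarts, seed=config.seed,
            )
        model_path = out / "model.json"
        save_model(
            fit, model_path, state_labels=reduced_space().labels,
            settings={"n_restarts": config.n_restarts, "seed": config.seed},
        )
        record("model", model_path)
        assign_path = out / "assignments.csv"
        assignments_frame(kept_ids, fit.gamma).to_csv(assign_path, index=False)
        record("assignments", assign_path)
        manifest["stages"]["fit"] = "ok"

        # --- stationary distributions --------------------------------------
        stage = "stationary"
        occ = occupancy_report(fit.model, labels=reduced_space().labels)
        occ_path = out / "stationary.csv"
        occ.to_csv(occ_path)
        record("stationary", occ_path)
        manifest["stages"]["stationary"] = "ok"

        # --- interventions --------------------------------------------------
        stage = "intervene"
        rows = []
        for target, beta in zip(("mood", "pain"), config.betas):
            spec_iv = InterventionSpec(target=target, beta=beta, split=config.split)
            for k, result in enumerate(intervention_report(fit.model, spec_iv)):
                for j, label in enumerate(reduced_space().labels):
                    rows.append(
                        {
                            "target": target,
                            "beta": beta,
                            "cluster": k + 1,
                            "state": label,
                            "x_before": result.x_before[j],
                            "x_after": result.x_after[j],
                            "delta": result.delta[j],
                        }
                    )
        iv_path = out / "intervention.csv"
        pd.DataFrame(rows).to_csv(iv_path, index=False)
        record("intervention", iv_path)
        manifest["stages"]["intervene"] = "ok"

        # --- covariate characterisation -------------------------------------
        stage = "characterise"
        if config.covariates_csv:
            covariates = pd.read_csv(
                config.covariates_csv, dtype={"participant_id": str}
            ).set_index("participant_id")
        if covariates is not None and len(covariates.columns):
            assignments = pd.Series(
                assign_clusters(fit.gamma), index=kept_ids, name="cluster"
            )
            char = characterise_clusters(assignments, covariates)
            char["cluster"] = char["cluster"] + 1
            char_path = out / "log_odds.csv"
            char.to_csv(char_path, index=False)
            record("log_odds", char_path)
            manifest["stages"]["characterise"] = "ok"
        else:
            manifest["stages"]["characterise"] = "skipped (no covariates)"

    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        logger.error("stage %s failed: %s", stage, exc)
        finish("failed", failed_stage=stage)
        raise

    return finish("ok")
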
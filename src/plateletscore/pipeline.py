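"""End-to-end pipeline orchestration.

``run_pipeline`` wires the stages in their analysis order — preprocess
(outlier screen + kNN imputation) → scoring (van der Waerden cumulative
scores and median splits) → association (batch rank correlations against
each variable block) → risk models (forest data with MH pooling, logistic
fits) → multivariate (stepwise LDA, canonical analysis, classifier panel) —
and writes every table with a provenance header (package version, seed,
config hash) so that a rerun with the same config reproduces the bundle
bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, generate_cohort
from .presets import study_config
from .preprocess import PreprocessReport, detect_outliers, impute_knn
from .scoring import SCORE_SETS, score_cohort
from .association import associate_score
from .risk import build_forest, fit_logistic
from .multivariate import PanelConfig, canonical, lda_rank, run_panel, vote_judges

__all__ = ["PipelineConfig", "run_pipeline"]

_ALL_STAGES = ("preprocess", "scoring", "association", "risk", "multivariate")


@dataclass
class PipelineConfig:
    """Pipeline recipe: input source, stage toggles, and stage parameters."""

    input_path: str | None = None        # cohort CSV; None -> simulate
    n_subjects: int = 251
    female_fraction: float = 125 / 251
    seed: int = 0
    missing_rate: float = 0.0
    stages: tuple[str, ...] = _ALL_STAGES
    scores: tuple[str, ...] = ("aggregation", "activation", "global")
    association_against: tuple[str, ...] = ("morphology", "metabolic", "oxidative")
    outlier_method: str = "tukey"
    impute_k: int = 5
    alpha_gate: float = 0.05
    bootstrap_correlation: int = 2000
    bootstrap_ancova: int = 10000
    panel_evaluation: str = "loo"
    out_dir: str = "results/pipeline"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "scores", "association_against"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _write_table(df: pd.DataFrame, path: Path, header_meta: dict[str, Any]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in header_meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the artifact bundle in memory
    and writes the tables under ``config.out_dir``."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    meta = {
        "plateletscore_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    events: list[dict] = []
    bundle: dict[str, Any] = {"config": config, "meta": meta}

    # --- input ------------------------------------------------------------
    if config.input_path:
        table = CohortTable.from_csv(config.input_path)
        _log(f"[input] loaded {table.n_subjects} subjects from {config.input_path}")
    else:
        sim = study_config(
            n_subjects=config.n_subjects,
            female_fraction=config.female_fraction,
            seed=config.seed,
            missing_rate=config.missing_rate,
        )
        table = generate_cohort(sim)
        _log(f"[input] simulated {table.n_subjects} subjects (seed {config.seed})")
    required = [c for s in config.scores for c in SCORE_SETS[s].columns]
    missing_cols = sorted(set(required) - set(table.data.columns))
    if missing_cols:
        raise ValueError(
            f"stage scoring aborted: required reactivity columns missing: {missing_cols}"
        )
    bundle["cohort"] = table

    report = PreprocessReport()

    # --- preprocess ---------------------------------------------------------
    if "preprocess" in config.stages:
        t = time.time()
        numeric = [
            c for c in table.data.columns
            if c not in ("subject_id", "sex")
            and pd.api.types.is_numeric_dtype(table.data[c])
        ]
        for col in numeric:
            v = table.data[col].to_numpy(dtype=float)
            if np.isfinite(v).sum() < 5 or np.ptp(v[np.isfinite(v)]) == 0:
                continue
            flagged = detect_outliers(v, method=config.outlier_method)
            if flagged:
                report.outliers[col] = {
                    "method": config.outlier_method,
                    "indices": sorted(flagged),
                }
        table, report = impute_knn(table, k=config.impute_k, report=report)
        events.append(
            {
                "stage": "preprocess",
                "outlier_variables": len(report.outliers),
                "imputed_cells": len(report.imputations),
                "skipped": dict(report.skipped_variables),
            }
        )
        _log(
            f"[preprocess] {len(report.outliers)} variables with flagged outliers, "
            f"{len(report.imputations)} cells imputed "
            f"({time.time() - t:.1f}s)"
        )
    bundle["preprocess_report"] = report

    data = table.data
    scores = {}

    # --- scoring ------------------------------------------------------------
    if "scoring" in config.stages:
        t = time.time()
        data, scores = score_cohort(data, score_names=config.scores)
        _write_table(data, out_dir / "cohort_scored.csv", meta)
        events.append(
            {
                "stage": "scoring",
                "scores": {
                    s: {"median": cs.median, "class_counts": cs.class_counts}
                    for s, cs in scores.items()
                },
            }
        )
        _log(f"[scoring] {len(scores)} cumulative scores ({time.time() - t:.1f}s)")
    bundle["scored"] = data
    bundle["scores"] = scores

    # --- association --------------------------------------------------------
    if "association" in config.stages and scores:
        t = time.time()
        against = [c for s in config.association_against for c in table.variable_sets.get(s, [])]
        frames = []
        for s in config.scores:
            frames.append(
                associate_score(
                    data, f"cum_{s}", against,
                    B=config.bootstrap_correlation, seed=config.seed,
                    jackknife=False,
                )
            )
        assoc = pd.concat(frames, ignore_index=True)
        _write_table(assoc, out_dir / "associations.csv", meta)
        bundle["associations"] = assoc
        events.append({"stage": "association", "pairs": len(assoc)})
        _log(f"[association] {len(assoc)} correlations ({time.time() - t:.1f}s)")

    # --- risk models --------------------------------------------------------
    if "risk" in config.stages and scores:
        t = time.time()
        against = [c for s in config.association_against for c in table.variable_sets.get(s, [])]
        forests = {}
        for s in config.scores:
            fd = build_forest(data, f"class_{s}", against)
            forests[s] = fd
            _write_table(fd.to_frame(), out_dir / f"forest_{s}.csv", meta)
        bundle["forests"] = forests
        # joint logistic on the morphology/metabolic leads, age/sex adjusted
        leads = [c for c in ("plt", "pct", "p_lcr", "wbc", "uric_acid") if c in data.columns]
        if leads and "age" in data.columns:
            logit = fit_logistic(
                data, f"class_{config.scores[0]}", leads, adjustment=("age", "sex")
            )
            _write_table(logit.odds_ratios, out_dir / "logistic_or.csv", meta)
            bundle["logistic"] = logit
        events.append({"stage": "risk", "forests": list(forests)})
        _log(f"[risk] {len(forests)} forests ({time.time() - t:.1f}s)")

    # --- multivariate -------------------------------------------------------
    if "multivariate" in config.stages and scores:
        t = time.time()
        first = config.scores[0]
        cls = data[f"class_{first}"].to_numpy(dtype=int)
        mv: dict[str, Any] = {}
        rank_rows, canon_rows = [], []
        for set_name in config.association_against:
            cols = table.variable_sets.get(set_name, [])
            cols = [c for c in cols if c in data.columns]
            if len(cols) < 2:
                continue
            ranking = lda_rank(data[cols], cls, grouping=f"class_{first}")
            mv[f"lda_{set_name}"] = ranking
            for v in ranking.entered:
                rank_rows.append(
                    {
                        "set": set_name, "variable": v,
                        "partial_wilks_lambda": ranking.partial_lambda[v],
                        "p": ranking.partial_p[v],
                    }
                )
            reac_cols = [c for c in ("amax_aa", "amax_col", "amax_adp") if c in data.columns]
            if len(reac_cols) >= 2:
                cs = canonical(data[reac_cols], data[cols])
                mv[f"canonical_{set_name}"] = cs
                canon_rows.append(
                    {
                        "set1": "aggregometry", "set2": set_name,
                        "canonical_correlation": cs.correlations[0],
                        "canonical_determination": cs.determination[0],
                        "wilks_lambda": cs.wilks_lambda[0],
                        "p": cs.bartlett_p[0],
                        "extracted_variance_set1": cs.extracted_variance[0],
                        "extracted_variance_set2": cs.extracted_variance[1],
                        "total_redundancy_set1": cs.total_redundancy[0],
                        "total_redundancy_set2": cs.total_redundancy[1],
                        "best_contributors_set2": "; ".join(cs.contributors2),
                    }
                )
        if rank_rows:
            _write_table(pd.DataFrame(rank_rows), out_dir / "lda_ranking.csv", meta)
        if canon_rows:
            _write_table(pd.DataFrame(canon_rows), out_dir / "canonical.csv", meta)
        feat_cols = [
            c for s in config.association_against
            for c in table.variable_sets.get(s, [])
        ]
        panel = run_panel(
            data[feat_cols], cls,
            PanelConfig(evaluation=config.panel_evaluation), seed=config.seed,
        )
        consensus = vote_judges(panel)
        mv["panel"] = panel
        mv["consensus"] = consensus
        panel_df = panel.predictions.copy()
        panel_df["consensus"] = consensus.consensus
        panel_df.insert(0, "subject_id", data["subject_id"].to_numpy()
                        if "subject_id" in data else np.arange(len(data)))
        _write_table(panel_df, out_dir / "panel_predictions.csv", meta)
        bundle["multivariate"] = mv
        events.append(
            {
                "stage": "multivariate",
                "panel_accuracy": panel.accuracy,
                "consensus_accuracy": consensus.accuracy,
            }
        )
        _log(
            f"[multivariate] panel {panel.accuracy} consensus "
            f"{consensus.accuracy:.1f}% ({time.time() - t:.1f}s)"
        )

    log_path = out_dir / "run_log.json"
    log_path.parent.mkdir(parents=True, exist_ok=True)
    log_path.write_text(
        json.dumps({"meta": meta, "events": events,
                    "elapsed_s": round(time.time() - t0, 2)},
                   indent=1, default=str)
    )
    _log(f"[done] {time.time() - t0:.1f}s; artifacts in {out_dir}")
    return bundle
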
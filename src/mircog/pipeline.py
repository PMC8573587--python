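"""End-to-end orchestration from a declarative run configuration.

Two pipelines are provided. The signature pipeline sequences the count
analysis in its fixed order — low-count filter, CPM/log2 normalization,
covariate residualization, sample-quality QC, eigen expression of the
signature set, then group comparison, phenotype correlation, clustering
and (optionally) the random-combination null. The maze pipeline turns a
trajectory table into trial features, strategy labels, per-day cognitive
scores and group density maps.

Every run writes a machine-readable manifest (config hash, input hashes,
seed, library versions) sufficient to reproduce it. A stage failure
aborts with the stage named; outputs produced before the failure are
retained with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, maze, meta, signature

logger = logging.getLogger("mircog")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run."""

    counts: str | None = None
    meta: str | None = None
    signature_set: str | None = None
    trajectories: str | None = None
    out_dir: str = "results"
    covariates: list[str] = field(default_factory=list)
    min_reads: int = 5
    min_fraction: float = 0.5
    qc_z: float = 2.5
    loading_threshold: float = 0.4
    k_max: int = 6
    step: int = 10
    n_combos: int = 1000
    alpha: float = 0.05
    group_column: str = "group"
    phenotype_column: str | None = None
    run_null: bool = False
    seed: int | None = None
    geometry: dict[str, Any] = field(default_factory=dict)
    max_duration: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        for attr in ("counts", "meta", "signature_set", "trajectories"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path for {attr!r} missing: {p}")
        return cfg

    def digest(self) -> str:
        payload = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _hash_file(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _manifest(config: RunConfig, inputs: list[str]) -> dict:
    return {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "inputs": {p: _hash_file(p) for p in inputs if p},
        "versions": {"mircog": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }


def _finalize(out_dir: Path, written: list[Path], failed: bool) -> None:
    if failed:
        for p in written:
            p.rename(p.with_suffix(p.suffix + ".partial"))


def run_signature_pipeline(config: RunConfig) -> dict:
    """Run the full signature analysis; returns the result bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        sample_meta = pd.read_csv(config.meta, index_col=0)
        sig = [line.strip() for line in Path(config.signature_set).read_text().splitlines()
               if line.strip()]
        missing_cov = [c for c in config.covariates if c not in sample_meta.columns]
        if missing_cov:
            raise KeyError(f"covariate columns missing from metadata: {missing_cov}")
        if config.group_column not in sample_meta.columns:
            raise KeyError(f"group column {config.group_column!r} missing")

        stage = "filter"
        logger.info("filter: min_reads=%d min_fraction=%.2f",
                    config.min_reads, config.min_fraction)
        counts = signature.filter_features(counts, config.min_reads,
                                           config.min_fraction)

        stage = "normalize"
        expr = signature.normalize_log2(counts)

        stage = "regress"
        if config.covariates:
            expr = signature.regress_out_covariates(expr, sample_meta,
                                                    config.covariates)

        stage = "qc"
        expr = signature.drop_outliers(expr, threshold=config.qc_z)

        stage = "eigen"
        score = signature.eigen_expression(expr, sig)
        scores_path = out_dir / "scores.csv"
        score.scores.rename("eigen_score").to_csv(scores_path)
        written.append(scores_path)

        stage = "tests"
        groups = sample_meta.loc[score.scores.index, config.group_column]
        w, p = signature.compare_groups(score, groups)
        results: dict[str, Any] = {
            "variance_explained": score.variance_explained,
            "wilcoxon": {"W": w, "p": p},
        }
        if config.phenotype_column:
            r, pr = signature.correlate_phenotype(
                score, sample_meta.loc[score.scores.index, config.phenotype_column])
            results["phenotype_correlation"] = {"r": r, "p": pr}

        stage = "cluster"
        seed = config.seed if config.seed is not None else 0
        k, assign, order = signature.cluster_scores(score, k_max=config.k_max,
                                                    seed=seed)
        results["clusters"] = {"k": k}
        clusters_path = out_dir / "clusters.csv"
        assign.rename("cluster").to_csv(clusters_path)
        written.append(clusters_path)

        if config.run_null:
            stage = "null"
            if config.seed is None:
                raise ValueError("seed required for the random-signature null")
            pool = [f for f in expr.index]
            table, pct = meta.random_signature_null(
                [(expr, groups)], pool, k=min(3, len(sig)),
                n_combos=config.n_combos, seed=config.seed,
                focal_signature=sig)
            null_path = out_dir / "null_table.tsv"
            table.assign(combo=table["combo"].map(lambda c: ";".join(c))).to_csv(
                null_path, sep="\t", index=False)
            written.append(null_path)
            results["null"] = {
                "focal_percentile": pct,
                "fraction_p_lt_alpha": float((table["p"] < config.alpha).mean()),
            }

        stage = "write"
        results_path = out_dir / "results.json"
        results_path.write_text(json.dumps(results, indent=2))
        written.append(results_path)
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(
            _manifest(config, [config.counts, config.meta, config.signature_set]),
            indent=2))
        written.append(manifest_path)
        return results
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        _finalize(out_dir, written, failed=True)
        raise PipelineError(stage, exc) from exc


def run_maze_pipeline(config: RunConfig) -> dict:
    """Trajectory table -> features, labels, daily scores, density maps."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        geo = maze.PoolGeometry(**config.geometry)
        trials = maze.read_trajectories_csv(config.trajectories, geo)
        if trials.empty:
            raise ValueError("trajectory file contains no trials")

        stage = "features"
        feats = pd.DataFrame([maze.extract_trial_features(tr).as_dict()
                              for tr in trials["trajectory"]],
                             index=trials["trial_id"])
        feats_path = out_dir / "features.tsv"
        feats.to_csv(feats_path, sep="\t")
        written.append(feats_path)

        stage = "classify"
        ruleset = maze.default_ruleset(geo, max_duration=config.max_duration)
        trials = trials.assign(strategy=[
            maze.classify_strategy(maze.extract_trial_features(tr), ruleset)
            for tr in trials["trajectory"]])
        labels_path = out_dir / "labels.tsv"
        trials.drop(columns="trajectory").to_csv(labels_path, sep="\t", index=False)
        written.append(labels_path)

        stage = "daily_scores"
        group_col = "group" if "group" in trials.columns else None
        daily = []
        for (day, *grp), sub in trials.groupby(
                ["day"] + ([group_col] if group_col else [])):
            sub = sub.copy()
            sub["trial_no"] = sub.groupby("mouse_id").cumcount()
            table = sub.pivot(index="mouse_id", columns="trial_no",
                              values="strategy")
            rec = {"day": day, "score": maze.daily_cognitive_score(table)}
            if grp:
                rec["group"] = grp[0]
            daily.append(rec)
        daily_df = pd.DataFrame(daily)
        daily_path = out_dir / "daily_scores.tsv"
        daily_df.to_csv(daily_path, sep="\t", index=False)
        written.append(daily_path)

        stage = "density"
        groups = trials[group_col] if group_col else pd.Series(
            "all", index=trials.index)
        maps = maze.occupancy_density(list(trials["trajectory"]), list(groups))
        for g, dm in maps.items():
            p = out_dir / f"density_{g}.tsv"
            np.savetxt(p, dm.grid, delimiter="\t")
            written.append(p)

        stage = "write"
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(
            _manifest(config, [config.trajectories]), indent=2))
        written.append(manifest_path)
        return {"n_trials": len(trials),
                "daily_scores": daily_df.to_dict(orient="records"),
                "strategy_counts": trials["strategy"].value_counts().to_dict()}
    except Exception as exc:  # noqa: BLE001
        _finalize(out_dir, written, failed=True)
        raise PipelineError(stage, exc) from exc
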
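"""Umbrella pipeline: simulate -> preprocess -> featurize -> evaluate.

A single :class:`PipelineConfig` (YAML round-trippable) drives the whole
chain; one root seed feeds named substreams for each stage so a single
integer reproduces a full experiment. The featurization stage caches its
output table keyed by a digest of the stage configuration, so re-runs with
an unchanged configuration skip simulation entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import ecnn
from .synthdata import simulate_dataset, default_environment, EnvironmentConfig
from .preprocess import baseline_correct
from .features import extract_features
from .selection import SelectionConfig
from .evaluation import EvalConfig, EvalReport, run_experiment
from .io import write_feature_table, read_feature_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed",
           "simulate_feature_table"]

log = logging.getLogger("enoserot")

_STAGES = ("simulate", "split", "select", "train", "evaluate")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything one experiment needs, with documented defaults."""

    environment: str = "laboratory"  # or "storage"
    n_per_class: int = 100
    seed: int = 0
    epochs: int = 300
    n_repeats: int = 5
    discretization: bool = True
    run_selection: bool = True
    mi_bins: int = 8
    alpha: float = 1.0
    beta: float = 1.0
    filter_quantile: float = 0.25
    cv_folds: int = 5
    out_dir: str = "enoserot-out"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one run: config digest plus stage artifact digests."""

    config_digest: str
    artifacts: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, path: Path) -> None:
        self.artifacts[stage] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        self.timestamps[stage] = time.time()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config_digest, "artifacts": self.artifacts,
             "timestamps": self.timestamps}, indent=1))


def simulate_feature_table(cfg: PipelineConfig, cache_dir: Path | None = None):
    """Simulate records and extract the 144-column feature table.

    With ``cache_dir`` set, the table is cached under a digest of the
    simulation-relevant settings and reused on identical re-runs.
    """
    sim_key = hashlib.sha256(
        f"{cfg.environment}:{cfg.n_per_class}:{cfg.seed}".encode()).hexdigest()[:16]
    if cache_dir is not None:
        cached = Path(cache_dir) / f"features-{sim_key}.csv"
        if cached.exists():
            log.info("simulate: cache hit (%s)", cached.name)
            return read_feature_table(cached), sim_key
    env = default_environment(cfg.environment, seed=cfg.seed)
    t0 = time.time()
    records = simulate_dataset(cfg.n_per_class, env,
                               seed=stage_seed(cfg.seed, "simulate"))
    table = extract_features([baseline_correct(r) for r in records])
    log.info("simulate+featurize: %d records in %.1fs", len(records), time.time() - t0)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        write_feature_table(table, Path(cache_dir) / f"features-{sim_key}.csv")
    return table, sim_key


def run_pipeline(cfg: PipelineConfig, use_cache: bool = True) -> EvalReport:
    """Execute the full chain and return the evaluation report.

    Stage errors propagate with the stage name prefixed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg.digest())

    stage = "simulate"
    try:
        table, sim_key = simulate_feature_table(cfg, out if use_cache else None)
        if use_cache:
            manifest.record(stage, out / f"features-{sim_key}.csv")

        stage = "evaluate"
        conditions = ("raw", "discretized") if cfg.discretization else ("raw",)
        ecfg = EvalConfig(
            n_repeats=cfg.n_repeats,
            seed=stage_seed(cfg.seed, "split"),
            selection=SelectionConfig(
                alpha=cfg.alpha, beta=cfg.beta, mi_bins=cfg.mi_bins,
                filter_quantile=cfg.filter_quantile, cv_folds=cfg.cv_folds,
                min_features=10, seed=stage_seed(cfg.seed, "select")),
            ensemble=ecnn.EnsembleConfig(
                train=ecnn.TrainConfig(epochs=cfg.epochs,
                                       seed=stage_seed(cfg.seed, "train"))),
            conditions=conditions,
            run_selection=cfg.run_selection,
        )
        t0 = time.time()
        report = run_experiment(table, ecfg)
        log.info("evaluate: %d cells in %.1fs", len(report.cells), time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(report_to_json(report))
    manifest.record("evaluate", out / "report.json")
    manifest.write(out / "manifest.json")
    return report


def report_to_json(report: EvalReport) -> str:
    payload = {
        "cells": {
            f"{m}/{c}": {
                "train_accuracies": cell.train_accuracies,
                "test_accuracies": cell.test_accuracies,
                "mean": cell.mean if cell.test_accuracies else None,
                "std": cell.std if cell.test_accuracies else None,
                "best_confusion": None if cell.best_confusion is None
                else cell.best_confusion.tolist(),
                "best_seed": cell.best_seed,
                "error": cell.error,
            }
            for (m, c), cell in report.cells.items()
        },
        "base_test_accuracies": report.base_test_accuracies,
        "selected_counts": report.selected_counts,
        "seeds": report.seeds,
    }
    return json.dumps(payload, indent=1)
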
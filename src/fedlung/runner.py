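"""Config-driven experiment execution and artifact writing.

Each runner resolves an ExperimentConfig into cohort → split → topology →
federation, writes its outputs (JSON/CSV, model parameters, the validation
matrix) into the target directory, and always drops the exact resolved
config and a run.log beside them so any artifact directory is
self-describing and re-runnable.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np

from .aggregation import FederationResult, run_federation
from .cohort import generate_cohort, write_cohort, split_cohort
from .config import ExperimentConfig, save_config
from .evaluation import (
    ComparisonResult,
    ScalingResult,
    compare_centralized_decentralized,
    confusion_matrix,
    metrics,
    node_scaling,
    prepare_federation,
    write_confusion_csv,
)
from .model import predict, save_params

log = logging.getLogger("fedlung")


def _setup_dir(cfg: ExperimentConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    if not log.handlers:
        log.setLevel(logging.INFO)
        log.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    return out


def _teardown_logging() -> None:
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def generate_experiment_cohort(cfg: ExperimentConfig, out_dir: str | Path) -> None:
    """Generate the configured cohort and write PNGs + manifests to disk."""
    out = _setup_dir(cfg, out_dir)
    try:
        cohort = generate_cohort(
            cfg.cohort.n_cases,
            cfg.cohort.class_mix,
            cfg.cohort.generator_params(),
            cfg.seeds.cohort_seed,
        )
        train, test = split_cohort(cohort, cfg.train_fraction, cfg.seeds.split_seed)
        split_map = {c.image.case_id: "train" for c in train}
        split_map.update({c.image.case_id: "test" for c in test})
        write_cohort(cohort, out, split_map=split_map)
        log.info("cohort of %d cases written to %s", len(cohort), out)
    finally:
        _teardown_logging()


def _run_core(cfg: ExperimentConfig) -> tuple[FederationResult, tuple]:
    cohort = generate_cohort(
        cfg.cohort.n_cases,
        cfg.cohort.class_mix,
        cfg.cohort.generator_params(),
        cfg.seeds.cohort_seed,
    )
    setup = prepare_federation(
        cohort,
        n_clients=cfg.topology.n_clients,
        n_routers=cfg.topology.n_routers,
        train_fraction=cfg.train_fraction,
        calibration_fraction=cfg.calibration_fraction,
        scheme=cfg.topology.partition,
        skew_alpha=cfg.topology.skew_alpha,
        split_seed=cfg.seeds.split_seed,
        partition_seed=cfg.seeds.partition_seed,
    )
    train_cfg = cfg.training.__class__(**{**cfg.training.__dict__, "seed": cfg.seeds.train_seed})
    result = run_federation(
        setup.topology,
        setup.shards,
        setup.calibration_set,
        setup.test_set,
        cfg.rounds,
        train_cfg,
        cfg.policy,
        cfg.seeds.init_seed,
        setup.scaler,
        cfg.architecture,
    )
    return result, setup.test_set


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> FederationResult:
    """Run the federated pipeline and write metrics, round log, R and params."""
    out = _setup_dir(cfg, out_dir)
    try:
        result, (test_x, test_y) = _run_core(cfg)
        for entry in result.round_log:
            log.info(
                "round=%d admitted=%s fallback=%s aggregate_norm=%.6f test_acc=%.4f",
                entry["round"],
                entry["admitted"],
                entry["fallback"],
                entry["aggregate_norm"],
                entry["test_accuracy"],
            )
        cm = confusion_matrix(test_y, predict(result.final_params, test_x))
        _json_dump(metrics(cm).to_dict(), out / "metrics.json")
        write_confusion_csv(cm, out / "confusion.csv")
        with open(out / "rounds.jsonl", "w") as fh:
            for entry in result.round_log:
                fh.write(json.dumps(entry) + "\n")
        result.matrix.to_frame().to_csv(out / "validation_matrix.csv", lineterminator="\n")
        save_params(result.final_params, out / "model.txt")
        return result
    finally:
        _teardown_logging()


def compare_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> ComparisonResult:
    """Centralized vs decentralized arms on one cohort; paired reports."""
    out = _setup_dir(cfg, out_dir)
    try:
        cohort = generate_cohort(
            cfg.cohort.n_cases,
            cfg.cohort.class_mix,
            cfg.cohort.generator_params(),
            cfg.seeds.cohort_seed,
        )
        train_cfg = cfg.training.__class__(
            **{**cfg.training.__dict__, "seed": cfg.seeds.train_seed}
        )
        res = compare_centralized_decentralized(
            cohort,
            n_clients=cfg.topology.n_clients,
            n_routers=cfg.topology.n_routers,
            rounds=cfg.rounds,
            cfg=train_cfg,
            policy=cfg.policy,
            arch=cfg.architecture,
            train_fraction=cfg.train_fraction,
            calibration_fraction=cfg.calibration_fraction,
            scheme=cfg.topology.partition,
            skew_alpha=cfg.topology.skew_alpha,
            split_seed=cfg.seeds.split_seed,
            partition_seed=cfg.seeds.partition_seed,
            init_seed=cfg.seeds.init_seed,
        )
        _json_dump(
            {
                "centralized": res.centralized_report.to_dict(),
                "decentralized": res.decentralized_report.to_dict(),
            },
            out / "comparison.json",
        )
        write_confusion_csv(res.centralized_cm, out / "confusion_centralized.csv")
        write_confusion_csv(res.decentralized_cm, out / "confusion_decentralized.csv")
        log.info(
            "centralized acc=%.4f decentralized acc=%.4f",
            res.centralized_report.accuracy,
            res.decentralized_report.accuracy,
        )
        return res
    finally:
        _teardown_logging()


def scale_experiment(
    cfg: ExperimentConfig,
    out_dir: str | Path,
    counts=(5, 10, 20, 40, 80, 160),
    per_node_min_shard: int = 12,
    plot: bool = False,
) -> ScalingResult:
    """Node-scaling sweep; one federated run per client count."""
    out = _setup_dir(cfg, out_dir)
    try:
        train_cfg = cfg.training.__class__(
            **{**cfg.training.__dict__, "seed": cfg.seeds.train_seed}
        )
        res = node_scaling(
            counts=tuple(counts),
            per_node_min_shard=per_node_min_shard,
            rounds=cfg.rounds,
            cfg=train_cfg,
            policy=cfg.policy,
            gen_params=cfg.cohort.generator_params(),
            seed=cfg.seeds.cohort_seed,
        )
        res.to_frame().to_csv(out / "scaling.csv", index=False, lineterminator="\n")
        if plot:
            from .evaluation import plot_scaling

            plot_scaling(res, out / "scaling.png")
        for row in res.rows:
            log.info(
                "n_nodes=%d accuracy=%.4f sensitivity=%.4f specificity=%.4f",
                row["n_nodes"],
                row["accuracy"],
                row["sensitivity_macro"],
                row["specificity_macro"],
            )
        return res
    finally:
        _teardown_logging()
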
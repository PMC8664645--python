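"""End-to-end orchestration: simulate/load → ridge maps → distill → decode → evaluate.

A run walks every ordered (seed, target) ROI pair and every feature table:
feature decoders are trained on the raw training activity (condition
``before``) and on the seed-residualized training activity (condition
``after``), predictions are made from category-averaged test samples, and the
paired Fisher-z statistics are arranged into effect matrices and corner
summaries. All randomness flows from one global seed through named
substreams, so a rerun with the same configuration is bit-identical; finished
seed–target pairs are persisted as fragments and skipped on resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ard import decode_feature, sample_units
from .datasets import (
    TrialDataset,
    ValidationError,
    average_by_category,
    load_container,
    roi_matrix,
)
from .distill import distill_pipeline
from .evaluate import build_effect_matrix, corner_means, unit_scores
from .ridge import DEFAULT_LAMBDA_GRID
from .simulate import SimConfig, generate

logger = logging.getLogger(__name__)

TASK_SPLITS = {"perception": "test_perception", "imagery": "test_imagery"}


def derive_seed(global_seed: int, name: str) -> int:
    """Named RNG substream seed (stable, < 2^31)."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one full distillation run."""

    out_dir: str
    container: Optional[str] = None        # input container path, or ...
    sim: Optional[SimConfig] = None        # ... simulator config
    roi_order: Optional[list] = None       # hierarchy low→high; default: data order
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    features: Optional[list] = None        # feature names; default: all tables
    n_units: Optional[int] = None          # default: all available, capped at 100
    unit_seed: Optional[int] = None        # default: derived from `seed`
    tasks: tuple = ("perception", "imagery")
    correction_m: Optional[int] = None     # Bonferroni family; default per matrix
    seed: int = 0
    resume: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.container is None) == (self.sim is None):
            raise ValidationError("provide exactly one of container / sim")
        bad = set(self.tasks) - set(TASK_SPLITS)
        if bad:
            raise ValidationError(f"unknown tasks {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        for key in ("tasks", "lambda_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(o)

        payload = dataclasses.asdict(self)
        # hash the semantic configuration only, not where it is written
        for transient in ("resume", "log_level", "out_dir"):
            payload.pop(transient, None)
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _train_block(dataset: TrialDataset):
    """Row indices and categories of train+validation, train first."""
    idx = np.concatenate(
        [
            np.flatnonzero(dataset.split_mask("train")),
            np.flatnonzero(dataset.split_mask("validation")),
        ]
    )
    return idx, dataset.trial_category[idx]


def _decode_conditions(
    train_activity, unit_values, test_blocks, unit_sample, feature, table
):
    """Fit decoders once, score against every task's averaged test block."""
    from .ard import predict_unit

    preds_by_task = {}
    models = None
    for task, (avg_activity, cats) in test_blocks.items():
        if models is None:
            preds, models = decode_feature(
                train_activity, unit_values, avg_activity, unit_sample.unit_ids
            )
        else:
            preds = np.column_stack(
                [predict_unit(m, avg_activity) for m in models]
            )
        truth = table.rows_for(cats)[:, list(unit_sample.unit_indices)]
        preds_by_task[task] = (preds, truth, cats)
    n_converged = sum(m.converged for m in models)
    return preds_by_task, models, n_converged


def run_all(config: RunConfig) -> dict:
    """Execute a full run; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frag_dir = out / "fragments"
    frag_dir.mkdir(exist_ok=True)
    chash = config.config_hash()

    if config.container is not None:
        dataset, tables = load_container(config.container)
    else:
        sim = dataclasses.replace(
            config.sim, rng_seed=derive_seed(config.seed, "simulate")
        ) if config.sim.rng_seed == 0 else config.sim
        dataset, tables, _ = generate(sim)

    roi_order = list(config.roi_order) if config.roi_order else dataset.roi_names
    missing = set(dataset.roi_names) - set(roi_order)
    if missing:
        raise ValidationError(f"roi_order does not cover ROIs {sorted(missing)}")
    tables = {t.feature_name: t for t in tables}
    feature_names = config.features or sorted(tables)
    tasks = [t for t in config.tasks if dataset.split_mask(TASK_SPLITS[t]).any()]

    unit_samples = {}
    for feature in feature_names:
        table = tables[feature]
        n = config.n_units if config.n_units is not None else min(100, table.n_units)
        useed = (
            config.unit_seed
            if config.unit_seed is not None
            else derive_seed(config.seed, f"units:{feature}")
        )
        unit_samples[feature] = sample_units(table, n, useed)

    train_idx, train_cats = _train_block(dataset)
    test_blocks_raw = {}
    for task in tasks:
        split = TASK_SPLITS[task]
        mask = dataset.split_mask(split)
        avg, cats = average_by_category(
            dataset.activity[mask], dataset.trial_category[mask]
        )
        test_blocks_raw[task] = (avg, cats)

    pairs = [
        (seed_roi, target_roi)
        for target_roi in roi_order
        for seed_roi in roi_order
        if seed_roi != target_roi
    ]
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
        "subject_id": dataset.subject_id,
        "roi_order": roi_order,
        "features": feature_names,
        "tasks": tasks,
        "conditions": ["before", "after"],
        "pairs": [list(p) for p in pairs],
        "stages": {},
        "files": {},
    }

    # --- baseline decoders, one per (feature, target ROI) -------------------
    baseline: dict = {}
    convergence_log: dict = {}
    for target_roi in roi_order:
        view = dataset.roi_view(target_roi)
        train_act = dataset.activity[np.ix_(train_idx, view.voxel_indices)]
        for feature in feature_names:
            us = unit_samples[feature]
            table = tables[feature]
            unit_vals = table.rows_for(train_cats)[:, list(us.unit_indices)]
            blocks = {
                task: (avg[:, list(view.voxel_indices)], cats)
                for task, (avg, cats) in test_blocks_raw.items()
            }
            preds_by_task, models, n_conv = _decode_conditions(
                train_act, unit_vals, blocks, us, feature, table
            )
            baseline[(target_roi, feature)] = preds_by_task
            convergence_log[f"before:{target_roi}:{feature}"] = n_conv
    manifest["stages"]["baseline_decode"] = "done"

    # --- distilled decoders per ordered pair ---------------------------------
    all_rows = []
    chosen_lambda: dict = {}
    for seed_roi, target_roi in pairs:
        frag = frag_dir / f"{target_roi}__{seed_roi}__{chash}.csv"
        if config.resume and frag.exists():
            all_rows.append(pd.read_csv(frag))
            logger.info("resume: skipping pair %s→%s", seed_roi, target_roi)
            continue
        residuals, rmap = distill_pipeline(
            dataset, seed_roi, target_roi, config.lambda_grid, roi_order
        )
        chosen_lambda[f"{seed_roi}->{target_roi}"] = rmap.ridge_lambda
        n_train_rows = int(dataset.split_mask("train").sum())
        distilled_train = np.vstack(
            [residuals["train"].residual, residuals["validation"].residual]
        ) if "validation" in residuals else residuals["train"].residual
        rows = []
        for feature in feature_names:
            us = unit_samples[feature]
            table = tables[feature]
            unit_vals = table.rows_for(train_cats)[:, list(us.unit_indices)]
            blocks = {}
            for task in tasks:
                split = TASK_SPLITS[task]
                mask = dataset.split_mask(split)
                avg, cats = average_by_category(
                    residuals[split].residual, dataset.trial_category[mask]
                )
                blocks[task] = (avg, cats)
            preds_by_task, models, n_conv = _decode_conditions(
                distilled_train, unit_vals, blocks, us, feature, table
            )
            convergence_log[f"after:{target_roi}<-{seed_roi}:{feature}"] = n_conv
            for task in tasks:
                preds_a, truth, cats = preds_by_task[task]
                preds_b, truth_b, _ = baseline[(target_roi, feature)][task]
                sb = unit_scores(
                    preds_b, truth_b, us.unit_ids, dataset.subject_id,
                    feature, "before",
                )
                sa = unit_scores(
                    preds_a, truth, us.unit_ids, dataset.subject_id,
                    feature, "after",
                )
                for b, a in zip(sb, sa):
                    rows.append(
                        {
                            "subject_id": dataset.subject_id,
                            "feature": feature,
                            "task": task,
                            "target": target_roi,
                            "seed": seed_roi,
                            "unit_id": b.unit_id,
                            "r_before": b.r,
                            "r_after": a.r,
                            "mae_before": b.mae,
                            "mae_after": a.mae,
                            "mse_before": b.mse,
                            "mse_after": a.mse,
                        }
                    )
        df = pd.DataFrame(rows)
        df.to_csv(frag, index=False)
        all_rows.append(df)
    scores = pd.concat(all_rows, ignore_index=True)
    scores_path = out / "unit_scores.csv"
    scores.to_csv(scores_path, index=False)
    manifest["stages"]["distill_decode"] = "done"
    manifest["chosen_lambda"] = chosen_lambda
    manifest["ard_converged"] = convergence_log

    # --- effect matrices and corners -----------------------------------------
    corners_rows = []
    for feature in feature_names:
        for task in tasks:
            sub = scores[(scores["feature"] == feature) & (scores["task"] == task)]
            em = build_effect_matrix(
                sub, feature, task, roi_order, config.correction_m
            )
            em.to_frame().to_csv(
                out / f"effect_matrix_{feature}_{task}.csv", index=False
            )
            if len(roi_order) >= 6:
                cs = corner_means(em)
                corners_rows.append(
                    {
                        "feature": feature,
                        "task": task,
                        "top_down_mean": cs.top_down_mean,
                        "bottom_up_mean": cs.bottom_up_mean,
                        "top_down_t": cs.top_down_test.t,
                        "top_down_p": cs.top_down_test.p,
                        "bottom_up_t": cs.bottom_up_test.t,
                        "bottom_up_p": cs.bottom_up_test.p,
                    }
                )
    if corners_rows:
        pd.DataFrame(corners_rows).to_csv(out / "corners.csv", index=False)
    manifest["stages"]["evaluate"] = "done"

    for path in sorted(out.glob("*.csv")):
        manifest["files"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_report(run_dir) -> pd.DataFrame:
    """Aggregate a finished run into one summary table (no new computation)."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"incomplete run: missing {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    missing = [
        name for name in manifest["files"] if not (run_dir / name).exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete run: missing artifacts {missing}")
    rows = []
    for feature in manifest["features"]:
        for task in manifest["tasks"]:
            path = run_dir / f"effect_matrix_{feature}_{task}.csv"
            df = pd.read_csv(path)
            rows.append(
                {
                    "feature": feature,
                    "task": task,
                    "n_cells": len(df),
                    "n_significant": int(df["significant"].sum()),
                    "mean_dz": float(df["mean_dz"].mean()),
                    "min_p": float(df["p"].min()),
                }
            )
    report = pd.DataFrame(rows)
    report.to_csv(run_dir / "report.csv", index=False)
    return report
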
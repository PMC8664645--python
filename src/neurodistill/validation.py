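"""Reference experiments validating the pipeline on the synthetic cortex.

Each function runs a self-contained experiment — oracle comparisons for the
ridge solver, planted-signal recovery for the sparse Bayesian decoder, and
replicated distillation runs measuring the sign and size of top-down /
bottom-up elimination effects — and returns plain dictionaries of summary
numbers. They are consumed by the test suite and by the repository's
acceptance script.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .ard import decode_feature, fit_ard
from .datasets import average_by_category
from .distill import distill_pipeline
from .evaluate import build_effect_matrix, fisher_z
from .pipeline import derive_seed
from .ridge import fit_ridge
from .simulate import SimConfig, generate


def ridge_oracle_error(n_instances: int = 50, seed: int = 0) -> float:
    """Worst-case |weights − oracle| over random ridge instances.

    The oracle solves each target voxel independently by least squares on the
    λ-augmented design ``[S; √λ·I]`` (QR path), fully independent of the
    joint normal-equations factorization under test.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(10, 101))
        p = int(rng.integers(2, 31))
        q = int(rng.integers(1, 31))
        lam = float(10.0 ** rng.uniform(-3, 3))
        seed_mat = rng.standard_normal((n, p))
        target = rng.standard_normal((n, q))
        rm = fit_ridge(seed_mat, target, lam)
        S = seed_mat - seed_mat.mean(axis=0)
        T = target - target.mean(axis=0)
        aug = np.vstack([S, np.sqrt(lam) * np.eye(p)])
        rhs = np.vstack([T, np.zeros((p, q))])
        oracle = np.linalg.lstsq(aug, rhs, rcond=None)[0]
        worst = max(worst, float(np.abs(rm.weights - oracle).max()))
    return worst


def ard_recovery(
    n_replicates: int = 20,
    n: int = 300,
    d: int = 120,
    k: int = 8,
    snr: float = 5.0,
    seed: int = 0,
) -> dict:
    """Planted k-sparse recovery: weight correlation and true-zero pruning."""
    rng = np.random.default_rng(seed)
    corrs, prunes = [], []
    for _ in range(n_replicates):
        X = rng.standard_normal((n, d))
        w = np.zeros(d)
        informative = rng.choice(d, size=k, replace=False)
        w[informative] = rng.normal(0.0, 1.0, size=k)
        signal = X @ w
        noise_sd = np.std(signal) / np.sqrt(snr)
        t = signal + rng.normal(0.0, noise_sd, size=n)
        model = fit_ard(X, t)
        corrs.append(float(np.corrcoef(model.weights, w)[0, 1]))
        true_zeros = np.setdiff1d(np.arange(d), informative)
        prunes.append(float(np.mean(model.weights[true_zeros] == 0.0)))
    return {
        "median_weight_corr": float(np.median(corrs)),
        "median_prune_rate": float(np.median(prunes)),
        "n_replicates": n_replicates,
    }


def _train_rows(dataset):
    idx = np.concatenate(
        [
            np.flatnonzero(dataset.split_mask("train")),
            np.flatnonzero(dataset.split_mask("validation")),
        ]
    )
    return idx, dataset.trial_category[idx]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan  # degenerate (e.g. fully pruned decoder): undefined r
    return float(np.corrcoef(a, b)[0, 1])


def _decode_roi(dataset, table, roi, train_activity, test_avg, test_cats,
                unit_idx):
    """Unit-wise test correlations of ARD decoders for one ROI/feature."""
    _, cats_tr = _train_rows(dataset)
    unit_vals = table.rows_for(cats_tr)[:, unit_idx]
    preds, _ = decode_feature(train_activity, unit_vals, test_avg)
    truth = table.rows_for(test_cats)[:, unit_idx]
    return np.array(
        [_safe_corr(preds[:, u], truth[:, u]) for u in range(len(unit_idx))]
    )


def _pooled_test(dz: np.ndarray) -> dict:
    res = stats.ttest_1samp(dz, 0.0)
    return {
        "mean_dz": float(dz.mean()),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(dz.size),
    }


def perception_sign_experiment(
    n_replicates: int = 20, seed: int = 0, n_units: Optional[int] = None
) -> dict:
    """Perception-task distillation signs at the default study conditions.

    For each replicate subject: decode layer-1 features from V1 before and
    after distilling (a) the most distant high-region seed (PPA) and (b) the
    adjacent seed (V2). Fisher-z paired differences are pooled across units
    and replicates. Expected under the generative law: distant-seed removal
    strips top-down contamination (positive effect); adjacent-seed removal
    strips shared feedforward signal (negative effect).
    """
    distant, adjacent = [], []
    for rep in range(n_replicates):
        cfg = SimConfig(
            mode="perception", rng_seed=derive_seed(seed, f"perception:{rep}")
        )
        dataset, tables, _ = generate(cfg)
        table = tables[0]  # layer-1 features
        n_u = n_units if n_units is not None else table.n_units
        unit_idx = list(range(n_u))
        tr_idx, _ = _train_rows(dataset)
        view = dataset.roi_view("V1")
        raw_train = dataset.activity[np.ix_(tr_idx, view.voxel_indices)]
        mask = dataset.split_mask("test_perception")
        avg_raw, cats = average_by_category(
            dataset.activity[np.ix_(mask.nonzero()[0], view.voxel_indices)],
            dataset.trial_category[mask],
        )
        r_before = _decode_roi(
            dataset, table, "V1", raw_train, avg_raw, cats, unit_idx
        )
        for seed_roi, bucket in (("PPA", distant), ("V2", adjacent)):
            residuals, _ = distill_pipeline(dataset, seed_roi, "V1")
            dist_train = np.vstack(
                [residuals["train"].residual, residuals["validation"].residual]
            )
            avg_dist, _ = average_by_category(
                residuals["test_perception"].residual,
                dataset.trial_category[mask],
            )
            r_after = _decode_roi(
                dataset, table, "V1", dist_train, avg_dist, cats, unit_idx
            )
            bucket.append(fisher_z(r_after) - fisher_z(r_before))
    return {
        "distant_seed": _pooled_test(np.concatenate(distant)),
        "adjacent_seed": _pooled_test(np.concatenate(adjacent)),
        "n_replicates": n_replicates,
    }


def imagery_corner_experiment(
    n_replicates: int = 20, seed: int = 0, units_per_cell: int = 8
) -> dict:
    """Imagery-task top-down-corner distillation effects, per feature layer.

    The corner pools the 9 cells (3 lowest targets × 3 highest seeds) of the
    effect matrix. Under the generative law the top-down replay carries the
    apex layers at removable strength, so those layers show negative pooled
    effects; layers the replay does not route stay null.
    """
    cfg0 = SimConfig()
    K = cfg0.n_regions
    rois = cfg0.roi_names
    targets = rois[:3]
    seeds = rois[K - 3:]
    n_layers = cfg0.n_feature_layers
    dz = {layer: [] for layer in range(1, n_layers + 1)}
    for rep in range(n_replicates):
        cfg = SimConfig(rng_seed=derive_seed(seed, f"imagery:{rep}"))
        dataset, tables, _ = generate(cfg)
        tr_idx, _ = _train_rows(dataset)
        mask = dataset.split_mask("test_imagery")
        rows = mask.nonzero()[0]
        unit_idx = list(range(units_per_cell))
        r_before = {}
        for target in targets:
            view = dataset.roi_view(target)
            raw_train = dataset.activity[np.ix_(tr_idx, view.voxel_indices)]
            avg_raw, cats = average_by_category(
                dataset.activity[np.ix_(rows, view.voxel_indices)],
                dataset.trial_category[mask],
            )
            for layer, table in enumerate(tables, start=1):
                r_before[(target, layer)] = _decode_roi(
                    dataset, table, target, raw_train, avg_raw, cats, unit_idx
                )
        for target in targets:
            for seed_roi in seeds:
                residuals, _ = distill_pipeline(dataset, seed_roi, target)
                dist_train = np.vstack(
                    [
                        residuals["train"].residual,
                        residuals["validation"].residual,
                    ]
                )
                avg_dist, cats = average_by_category(
                    residuals["test_imagery"].residual,
                    dataset.trial_category[mask],
                )
                for layer, table in enumerate(tables, start=1):
                    r_after = _decode_roi(
                        dataset, table, target, dist_train, avg_dist, cats,
                        unit_idx,
                    )
                    dz[layer].append(
                        fisher_z(r_after) - fisher_z(r_before[(target, layer)])
                    )
    return {
        f"layer{layer}": _pooled_test(np.concatenate(dz[layer]))
        for layer in dz
    }


def null_sim_config(rng_seed: int = 0) -> SimConfig:
    """Fully uncoupled small cortex: no top-down, no cascade, no shared gain,
    one private feature layer per region."""
    return SimConfig(
        n_regions=4,
        voxels_per_region=24,
        n_train_categories=100,
        n_test_categories=25,
        train_trials=400,
        test_reps_perception=8,
        test_reps_imagery=2,
        n_feature_layers=4,
        units_per_layer=12,
        kappa_td=0.0,
        crosstalk_gain=0.0,
        global_signal_sd=0.0,
        mode="perception",
        rng_seed=rng_seed,
    )


def null_false_positive_experiment(
    n_replicates: int = 20, seed: int = 0, n_units: int = 8
) -> dict:
    """Distillation effects when regions are fully uncoupled.

    Every seed–target prediction is then pure noise, residuals match the raw
    activity, and no effect-matrix cell should survive Bonferroni correction.
    Returns the fraction of replicates with at least one flagged cell.
    """
    features = ["layer1", "layer4"]
    flagged = 0
    total_cells = 0
    total_sig = 0
    for rep in range(n_replicates):
        cfg = null_sim_config(rng_seed=derive_seed(seed, f"null:{rep}"))
        dataset, tables, _ = generate(cfg)
        tables = {t.feature_name: t for t in tables}
        rois = dataset.roi_names
        tr_idx, _ = _train_rows(dataset)
        mask = dataset.split_mask("test_perception")
        rows_test = mask.nonzero()[0]
        unit_idx = list(range(n_units))
        r_before = {}
        for target in rois:
            view = dataset.roi_view(target)
            raw_train = dataset.activity[np.ix_(tr_idx, view.voxel_indices)]
            avg_raw, cats = average_by_category(
                dataset.activity[np.ix_(rows_test, view.voxel_indices)],
                dataset.trial_category[mask],
            )
            for feat in features:
                r_before[(target, feat)] = _decode_roi(
                    dataset, tables[feat], target, raw_train, avg_raw, cats,
                    unit_idx,
                )
        records = []
        for target in rois:
            for seed_roi in rois:
                if seed_roi == target:
                    continue
                residuals, _ = distill_pipeline(dataset, seed_roi, target)
                dist_train = np.vstack(
                    [
                        residuals["train"].residual,
                        residuals["validation"].residual,
                    ]
                )
                avg_dist, cats = average_by_category(
                    residuals["test_perception"].residual,
                    dataset.trial_category[mask],
                )
                for feat in features:
                    r_after = _decode_roi(
                        dataset, tables[feat], target, dist_train, avg_dist,
                        cats, unit_idx,
                    )
                    for u in range(n_units):
                        records.append(
                            {
                                "target": target,
                                "seed": seed_roi,
                                "subject_id": dataset.subject_id,
                                "unit_id": u,
                                "r_before": r_before[(target, feat)][u],
                                "r_after": r_after[u],
                                "feature": feat,
                            }
                        )
        scores = pd.DataFrame(records)
        n_sig = 0
        for feat in features:
            em = build_effect_matrix(
                scores[scores["feature"] == feat], feat, "perception", rois
            )
            n_sig += int(em.significant.sum())
            total_cells += int(np.isfinite(em.p_values).sum())
        total_sig += n_sig
        flagged += int(n_sig > 0)
    return {
        "flagged_replicates": flagged,
        "n_replicates": n_replicates,
        "clean_fraction": 1.0 - flagged / n_replicates,
        "significant_cells": total_sig,
        "tested_cells": total_cells,
    }
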
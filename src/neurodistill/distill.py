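"""Distillation: subtract the seed-predicted activity from a target ROI.

The observed target activity is modeled as the sum of the component a seed
region can linearly explain and a residual "latent" component::

    X*_target = X_seed→target + X_latent

The residual is what remains of the target's information once the
top-down/bottom-up signal attributable to the seed has been eliminated; it is
subsequently fed to the feature decoders in place of the raw activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datasets import SPLITS, TrialDataset, ValidationError, roi_matrix
from .ridge import DEFAULT_LAMBDA_GRID, RidgeMap, fit_ridge, predict_target, score_r2


@dataclass
class DistilledDataset:
    """Residual target-ROI activity with provenance of the removed seed."""

    target_roi: str
    seed_roi: str
    residual: np.ndarray       # (trials_in_split, n_target_voxels)
    split: str
    ridge_lambda: float
    direction: str             # top_down_removed | bottom_up_removed

    def __post_init__(self) -> None:
        if not self.target_roi or not self.seed_roi:
            raise ValidationError("provenance fields must be non-empty")


def distill(
    target: np.ndarray,
    predicted: np.ndarray,
    *,
    target_roi: str,
    seed_roi: str,
    split: str,
    ridge_lambda: float = float("nan"),
    direction: str = "unspecified",
) -> DistilledDataset:
    """Elementwise residual ``target − predicted`` with provenance."""
    target = np.asarray(target, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if target.shape != predicted.shape:
        raise ValidationError(
            f"shape mismatch: target {target.shape} vs predicted {predicted.shape}"
        )
    return DistilledDataset(
        target_roi=target_roi,
        seed_roi=seed_roi,
        residual=target - predicted,
        split=split,
        ridge_lambda=ridge_lambda,
        direction=direction,
    )


def _direction(roi_order: Sequence[str], seed_roi: str, target_roi: str) -> str:
    order = list(roi_order)
    return (
        "top_down_removed"
        if order.index(seed_roi) > order.index(target_roi)
        else "bottom_up_removed"
    )


def distill_pipeline(
    dataset: TrialDataset,
    seed_roi: str,
    target_roi: str,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    roi_order: Optional[Sequence[str]] = None,
) -> tuple[dict, RidgeMap]:
    """Fit, select λ, and residualize every split of a dataset.

    The map is fit on the ``train`` sub-split; λ is chosen by validation R² on
    the ``validation`` sub-split (if the dataset carries no explicit
    validation tag, the training rows are halved first/last in stored order).
    The selected map is then applied in-sample to train+validation rows and
    out-of-sample to each test split.

    Returns ``(residuals, ridge_map)`` where ``residuals`` maps each non-empty
    split tag to a :class:`DistilledDataset`.
    """
    from .ridge import select_lambda  # local import avoids cycle at module load

    roi_order = list(roi_order) if roi_order is not None else dataset.roi_names
    for roi in (seed_roi, target_roi):
        if roi not in roi_order:
            raise ValidationError(f"ROI {roi!r} not in roi_order {roi_order}")

    has_validation = bool(dataset.split_mask("validation").any())
    if has_validation:
        tr_seed = roi_matrix(dataset, seed_roi, "train")
        tr_target = roi_matrix(dataset, target_roi, "train")
        va_seed = roi_matrix(dataset, seed_roi, "validation")
        va_target = roi_matrix(dataset, target_roi, "validation")
    else:
        full_seed = roi_matrix(dataset, seed_roi, "train")
        full_target = roi_matrix(dataset, target_roi, "train")
        half = full_seed.shape[0] // 2
        tr_seed, va_seed = full_seed[:half], full_seed[half:]
        tr_target, va_target = full_target[:half], full_target[half:]

    best_lam, _ = select_lambda(tr_seed, tr_target, va_seed, va_target, lambda_grid)
    ridge_map = fit_ridge(
        tr_seed, tr_target, best_lam, seed_roi=seed_roi, target_roi=target_roi
    )
    ridge_map.validation_r2 = score_r2(
        predict_target(ridge_map, va_seed), va_target
    )[0]

    direction = _direction(roi_order, seed_roi, target_roi)
    residuals: dict = {}
    for split in SPLITS:
        if not dataset.split_mask(split).any():
            continue
        seed = roi_matrix(dataset, seed_roi, split)
        target = roi_matrix(dataset, target_roi, split)
        residuals[split] = distill(
            target,
            predict_target(ridge_map, seed),
            target_roi=target_roi,
            seed_roi=seed_roi,
            split=split,
            ridge_lambda=best_lam,
            direction=direction,
        )
    return residuals, ridge_map
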
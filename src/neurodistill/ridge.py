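"""Region-to-region decoding: ridge maps, R² scoring, trial connectivity.

Every voxel of the target ROI is modeled as a weighted linear summation of all
seed-ROI voxels. Because voxels within an ROI are strongly correlated, the
maps use L2-regularized least squares; the ridge parameter λ is selected by
maximizing mean validation R² on a held-out half of the training trials. All
target voxels share one factorization: with column-centered seed S and target
T,

    W = (SᵀS + λI)⁻¹ SᵀT,    intercepts restore the training means.

Trial-wise (beta-series) functional connectivity between ROI-mean activity
series is provided for comparison with the learned maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .datasets import TrialDataset, ValidationError, roi_matrix

logger = logging.getLogger(__name__)

#: Default λ grid: 9 points log-spaced over 10⁻²…10⁶.
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 6, 9))


@dataclass
class RidgeMap:
    """Fitted affine seed→target map (slopes ``a`` and offsets ``b``)."""

    seed_roi: str
    target_roi: str
    weights: np.ndarray          # (n_seed_voxels, n_target_voxels)
    intercepts: np.ndarray       # (n_target_voxels,)
    ridge_lambda: float
    seed_train_means: np.ndarray
    target_train_means: np.ndarray
    validation_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.weights.shape[1] != self.intercepts.shape[0]:
            raise ValidationError("weights/intercepts shape mismatch")
        if not np.isfinite(self.weights).all():
            raise ValidationError("non-finite ridge weights")


def fit_ridge(
    seed: np.ndarray,
    target: np.ndarray,
    lam: float,
    seed_roi: str = "seed",
    target_roi: str = "target",
) -> RidgeMap:
    """Fit the L2-penalized linear map from seed to target voxels.

    All target voxels are solved jointly from a single Cholesky factorization
    of ``SᵀS + λI`` on training-mean-centered data.
    """
    seed = np.asarray(seed, dtype=float)
    target = np.asarray(target, dtype=float)
    if seed.ndim != 2 or target.ndim != 2 or seed.shape[0] != target.shape[0]:
        raise ValidationError("seed/target must be 2-D with equal row counts")
    if seed.shape[0] < 2:
        raise ValidationError("need at least 2 training trials")
    if lam <= 0:
        raise ValidationError("ridge lambda must be positive")
    if not (np.isfinite(seed).all() and np.isfinite(target).all()):
        raise ValidationError("non-finite input")
    mu_s = seed.mean(axis=0)
    mu_t = target.mean(axis=0)
    S = seed - mu_s
    T = target - mu_t
    gram = S.T @ S
    gram[np.diag_indices_from(gram)] += lam
    weights = cho_solve(cho_factor(gram, lower=True), S.T @ T)
    intercepts = mu_t - mu_s @ weights
    return RidgeMap(
        seed_roi=seed_roi,
        target_roi=target_roi,
        weights=weights,
        intercepts=intercepts,
        ridge_lambda=float(lam),
        seed_train_means=mu_s,
        target_train_means=mu_t,
    )


def predict_target(ridge_map: RidgeMap, seed: np.ndarray) -> np.ndarray:
    """Apply a fitted map: ``X_seed→target = seed·W + b``."""
    seed = np.asarray(seed, dtype=float)
    if seed.ndim != 2 or seed.shape[1] != ridge_map.weights.shape[0]:
        raise ValidationError(
            f"seed has {seed.shape[-1]} columns, map expects "
            f"{ridge_map.weights.shape[0]}"
        )
    return seed @ ridge_map.weights + ridge_map.intercepts


def score_r2(
    predicted: np.ndarray, actual: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-voxel and mean coefficient of determination.

    ``R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²`` per voxel; may be negative out of sample.
    Zero-variance voxels have undefined R² (NaN) and are excluded from the
    mean with a logged count.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValidationError("shape mismatch")
    if actual.shape[0] < 2:
        raise ValidationError("need at least 2 rows to score")
    ss_res = ((actual - predicted) ** 2).sum(axis=0)
    ss_tot = ((actual - actual.mean(axis=0)) ** 2).sum(axis=0)
    per_voxel = np.full(actual.shape[1], np.nan)
    ok = ss_tot > 0
    per_voxel[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("score_r2: excluded %d zero-variance voxels", n_bad)
    if not ok.any():
        raise ValidationError("all voxels have zero variance")
    return float(per_voxel[ok].mean()), per_voxel


def select_lambda(
    train_seed: np.ndarray,
    train_target: np.ndarray,
    val_seed: np.ndarray,
    val_target: np.ndarray,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> tuple[float, dict]:
    """Pick the grid λ maximizing mean validation R²; ties favor larger λ."""
    grid = list(grid)
    if not grid:
        raise ValidationError("empty lambda grid")
    scores: dict = {}
    best_lam, best_r2 = None, -np.inf
    for lam in sorted(grid):
        rm = fit_ridge(train_seed, train_target, lam)
        r2, _ = score_r2(predict_target(rm, val_seed), val_target)
        scores[float(lam)] = r2
        if r2 >= best_r2:  # >= so ties break toward larger λ
            best_lam, best_r2 = float(lam), r2
    return best_lam, scores


def connectivity(
    dataset: TrialDataset, roi_a: str, roi_b: str, split: str
) -> float:
    """Trial-wise (beta-series) Pearson correlation of ROI-mean activity."""
    a = roi_matrix(dataset, roi_a, split).mean(axis=1)
    b = roi_matrix(dataset, roi_b, split).mean(axis=1)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("constant ROI-mean series: correlation undefined")
    return float(stats.pearsonr(a, b)[0])


def connectivity_matrix(
    dataset: TrialDataset, rois: Sequence[str], split: str
) -> np.ndarray:
    """Symmetric ROI×ROI connectivity matrix with unit diagonal."""
    n = len(rois)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = connectivity(dataset, rois[i], rois[j], split)
            mat[i, j] = mat[j, i] = r
    return mat
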
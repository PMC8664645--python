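"""Decoding metrics and paired distillation-effect statistics.

Per feature unit, decoding accuracy is the Pearson correlation between true
and predicted feature values over the test categories (MAE and MSE are kept
as scale-sensitive companions). Distillation effects are paired differences
of Fisher-z-transformed correlations (after − before), tested with a
two-sided one-sample t-test over pooled (subject × unit) pairs, arranged into
R×R seed–target effect matrices with Bonferroni family-wise error control,
and summarized by the means of the 3×3 corner blocks (top-down corner:
lowest-3 targets × highest-3 seeds; bottom-up corner: the transpose block).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class UnitScore:
    """Decoding accuracy of one feature unit in one condition."""

    subject_id: str
    feature_name: str
    unit_id: object
    condition: str          # "before" | "after"
    r: float                # Pearson r over test categories (NaN if undefined)
    mae: float
    mse: float


def unit_scores(
    predicted: np.ndarray,
    truth: np.ndarray,
    unit_ids: Sequence,
    subject_id: str = "",
    feature_name: str = "",
    condition: str = "",
) -> list:
    """Per-unit Pearson r, MAE and MSE across test categories.

    Zero-variance predicted or true units get ``r = NaN`` (recorded, excluded
    from paired tests downstream with a logged count).
    """
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValidationError("shape mismatch")
    if predicted.shape[0] < 3:
        raise ValidationError("need at least 3 categories")
    scores = []
    n_undefined = 0
    for u in range(predicted.shape[1]):
        p, y = predicted[:, u], truth[:, u]
        if np.std(p) == 0 or np.std(y) == 0:
            r = np.nan
            n_undefined += 1
        else:
            r = float(np.corrcoef(p, y)[0, 1])
        scores.append(
            UnitScore(
                subject_id=subject_id,
                feature_name=feature_name,
                unit_id=unit_ids[u],
                condition=condition,
                r=r,
                mae=float(np.abs(p - y).mean()),
                mse=float(((p - y) ** 2).mean()),
            )
        )
    if n_undefined:
        logger.info("unit_scores: %d units with undefined r", n_undefined)
    return scores


def fisher_z(r):
    """Variance-stabilizing Fisher transform ``z = atanh(r)``.

    Values with ``|r| ≥ 1`` are clipped to ``1 − 1e−15`` in magnitude with a
    warning.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("fisher_z: |r| >= 1 clipped", RuntimeWarning, stacklevel=2)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    df: int
    mean_dz: float
    n: int


def paired_effect_test(before, after) -> PairedTestResult:
    """Two-sided paired t-test on Fisher-z differences ``z(after) − z(before)``.

    Pairs with a missing (NaN) correlation on either side are dropped with a
    logged count. Degenerate zero-variance differences give ``t = 0, p = 1``
    when the mean difference is zero.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValidationError("before/after length mismatch")
    ok = np.isfinite(before) & np.isfinite(after)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("paired_effect_test: dropped %d incomplete pairs", n_dropped)
    before, after = before[ok], after[ok]
    n = before.size
    if n < 3:
        raise ValidationError("need at least 3 complete pairs")
    dz = fisher_z(after) - fisher_z(before)
    mean = float(dz.mean())
    sd = float(dz.std(ddof=1))
    df = n - 1
    if sd == 0:
        if mean == 0:
            return PairedTestResult(t=0.0, p=1.0, df=df, mean_dz=0.0, n=n)
        t = np.inf if mean > 0 else -np.inf
        return PairedTestResult(t=float(t), p=0.0, df=df, mean_dz=mean, n=n)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTestResult(t=float(t), p=float(p), df=df, mean_dz=mean, n=n)


@dataclass
class EffectMatrix:
    """R×R grid of distillation effects; rows targets, columns seeds."""

    feature_name: str
    task: str
    roi_order: list                   # low → high
    t_values: np.ndarray
    p_values: np.ndarray
    mean_dz: np.ndarray
    n_pairs: int
    bonferroni_m: int
    significant: np.ndarray           # boolean, FWE < 5%
    dz_pools: dict = field(repr=False, default_factory=dict)

    @property
    def n_rois(self) -> int:
        return len(self.roi_order)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (target, seed, t, p, mean_dz, significant)."""
        rows = []
        for i, target in enumerate(self.roi_order):
            for j, seed in enumerate(self.roi_order):
                if i == j:
                    continue
                rows.append(
                    {
                        "feature": self.feature_name,
                        "task": self.task,
                        "target": target,
                        "seed": seed,
                        "t": self.t_values[i, j],
                        "p": self.p_values[i, j],
                        "mean_dz": self.mean_dz[i, j],
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def build_effect_matrix(
    scores: pd.DataFrame,
    feature: str,
    task: str,
    roi_order: Sequence[str],
    correction_m: Optional[int] = None,
) -> EffectMatrix:
    """Assemble the seed×target effect matrix from paired unit scores.

    ``scores`` is a long table with columns ``target``, ``seed``,
    ``subject_id``, ``unit_id``, ``r_before``, ``r_after`` already restricted
    to one feature and task. Every off-diagonal (target, seed) pair must be
    present. ``correction_m`` defaults to the number of off-diagonal cells of
    one matrix (R·(R−1), per-matrix Bonferroni family).
    """
    roi_order = list(roi_order)
    R = len(roi_order)
    m = int(correction_m) if correction_m is not None else R * (R - 1)
    required = {
        (t, s) for i, t in enumerate(roi_order) for j, s in enumerate(roi_order)
        if i != j
    }
    have = set(map(tuple, scores[["target", "seed"]].drop_duplicates().to_numpy()))
    missing = sorted(required - have)
    if missing:
        raise ValidationError(f"missing seed–target pairs: {missing}")

    t_values = np.full((R, R), np.nan)
    p_values = np.full((R, R), np.nan)
    mean_dz = np.full((R, R), np.nan)
    significant = np.zeros((R, R), dtype=bool)
    dz_pools: dict = {}
    n_pairs = None
    for i, target in enumerate(roi_order):
        for j, seed in enumerate(roi_order):
            if i == j:
                continue
            cell = scores[(scores["target"] == target) & (scores["seed"] == seed)]
            ok = (
                np.isfinite(cell["r_before"]) & np.isfinite(cell["r_after"])
            ).to_numpy()
            dz_pools[(i, j)] = fisher_z(
                cell["r_after"].to_numpy()[ok]
            ) - fisher_z(cell["r_before"].to_numpy()[ok])
            if ok.sum() < 3:
                # nearly all units degenerate: cell undefined, not an error
                logger.warning(
                    "effect matrix %s/%s cell (%s, %s): only %d complete "
                    "pairs; recorded as undefined",
                    feature, task, target, seed, int(ok.sum()),
                )
                continue
            res = paired_effect_test(
                cell["r_before"].to_numpy(), cell["r_after"].to_numpy()
            )
            t_values[i, j] = res.t
            p_values[i, j] = res.p
            mean_dz[i, j] = res.mean_dz
            significant[i, j] = res.p * m < 0.05
            n_pairs = res.n if n_pairs is None else n_pairs
    return EffectMatrix(
        feature_name=feature,
        task=task,
        roi_order=roi_order,
        t_values=t_values,
        p_values=p_values,
        mean_dz=mean_dz,
        n_pairs=int(n_pairs) if n_pairs is not None else 0,
        bonferroni_m=m,
        significant=significant,
        dz_pools=dz_pools,
    )


@dataclass(frozen=True)
class CornerSummary:
    top_down_mean: float
    bottom_up_mean: float
    top_down_test: PairedTestResult
    bottom_up_test: PairedTestResult


def corner_means(matrix: EffectMatrix, block: int = 3) -> CornerSummary:
    """Means of the top-down and bottom-up 3×3 corner blocks.

    Top-down block: the ``block`` lowest ROIs as targets × the ``block``
    highest ROIs as seeds (upper-right of the matrix); bottom-up block is the
    transpose corner. One-sample two-sided t-tests run on the Δz values pooled
    over the underlying cells.
    """
    R = matrix.n_rois
    if R < 2 * block:
        raise ValidationError(f"need at least {2 * block} ROIs, have {R}")
    low = range(block)
    high = range(R - block, R)
    td_cells = [(i, j) for i in low for j in high]
    bu_cells = [(i, j) for i in high for j in low]

    def summarize(cells):
        mean = float(np.mean([matrix.mean_dz[c] for c in cells]))
        pooled = np.concatenate([matrix.dz_pools[c] for c in cells])
        n = pooled.size
        m, sd = float(pooled.mean()), float(pooled.std(ddof=1))
        if sd == 0:
            t, p = (0.0, 1.0) if m == 0 else (np.sign(m) * np.inf, 0.0)
        else:
            t = m / (sd / np.sqrt(n))
            p = 2.0 * stats.t.sf(abs(t), n - 1)
        return mean, PairedTestResult(
            t=float(t), p=float(p), df=n - 1, mean_dz=m, n=n
        )

    td_mean, td_test = summarize(td_cells)
    bu_mean, bu_test = summarize(bu_cells)
    return CornerSummary(
        top_down_mean=td_mean,
        bottom_up_mean=bu_mean,
        top_down_test=td_test,
        bottom_up_test=bu_test,
    )
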
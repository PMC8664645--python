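"""Core containers for trial-wise multivoxel activity and stimulus features.

The universal currency of the pipeline is a :class:`TrialDataset`: a trials ×
voxels matrix of run-normalized response amplitudes, with one category label,
one split tag and one run index per trial, and one ROI label per voxel.
Continuous stimulus-feature representations (e.g. CNN-layer unit activations
per category) travel alongside as :class:`FeatureTable` objects.

Containers persist either to a single HDF5 file or to a directory of
delimited-text files with the same logical schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid trial split tags, in canonical order.
SPLITS = ("train", "validation", "test_perception", "test_imagery")
TRAIN_SPLITS = ("train", "validation")
TEST_SPLITS = ("test_perception", "test_imagery")

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A persisted container is missing a required dataset or field."""


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


def _as_str_array(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.dtype.kind in ("S", "O"):
        arr = arr.astype(str)
    return arr.astype(str)


@dataclass
class FeatureTable:
    """Per-category continuous feature values (one row per category).

    Parameters
    ----------
    feature_name:
        Identifier of the feature type/layer (e.g. ``"layer1"``, ``"CNN3"``).
    values:
        ``(n_categories, n_units)`` float matrix of feature-unit values.
    category_ids:
        Integer category identifier per row.
    unit_ids:
        Unique identifier per column.
    """

    feature_name: str
    values: np.ndarray
    category_ids: np.ndarray
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.category_ids = np.asarray(self.category_ids, dtype=np.int64)
        self.unit_ids = np.asarray(self.unit_ids)
        if self.values.ndim != 2:
            raise ValidationError(f"{self.feature_name}: values must be 2-D")
        if self.values.shape[0] != self.category_ids.shape[0]:
            raise ValidationError(
                f"{self.feature_name}: {self.values.shape[0]} rows but "
                f"{self.category_ids.shape[0]} category ids"
            )
        if self.values.shape[1] != self.unit_ids.shape[0]:
            raise ValidationError(
                f"{self.feature_name}: {self.values.shape[1]} columns but "
                f"{self.unit_ids.shape[0]} unit ids"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"{self.feature_name}: non-finite value at "
                f"(category row {bad[0]}, unit column {bad[1]})"
            )
        if len(set(self.unit_ids.tolist())) != len(self.unit_ids):
            raise ValidationError(f"{self.feature_name}: unit_ids not unique")
        if len(set(self.category_ids.tolist())) != len(self.category_ids):
            raise ValidationError(f"{self.feature_name}: duplicate category rows")

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def rows_for(self, categories: Sequence[int]) -> np.ndarray:
        """Feature values aligned to an arbitrary sequence of category ids."""
        index = {int(c): i for i, c in enumerate(self.category_ids)}
        try:
            rows = [index[int(c)] for c in categories]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(
                f"{self.feature_name}: unknown category {exc.args[0]}"
            ) from exc
        return self.values[rows]


@dataclass(frozen=True)
class ROIView:
    """Stable, ordered index of one ROI's columns in a parent dataset."""

    roi_name: str
    voxel_indices: tuple

    def __len__(self) -> int:
        return len(self.voxel_indices)


@dataclass
class TrialDataset:
    """Trial-wise activity with per-trial and per-voxel labels.

    ``activity`` holds run-normalized amplitudes (percent signal change,
    unitless); rows are trials, columns voxels. Test-split categories must be
    disjoint from training/validation categories.
    """

    subject_id: str
    activity: np.ndarray
    trial_category: np.ndarray
    trial_split: np.ndarray
    trial_run: np.ndarray
    voxel_roi: np.ndarray

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.trial_category = np.asarray(self.trial_category, dtype=np.int64)
        self.trial_split = _as_str_array(self.trial_split)
        self.trial_run = np.asarray(self.trial_run, dtype=np.int64)
        self.voxel_roi = _as_str_array(self.voxel_roi)
        n, v = self.activity.shape
        for name, arr, size in (
            ("trial_category", self.trial_category, n),
            ("trial_split", self.trial_split, n),
            ("trial_run", self.trial_run, n),
            ("voxel_roi", self.voxel_roi, v),
        ):
            if arr.shape != (size,):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({size},)"
                )
        if not np.isfinite(self.activity).all():
            bad = np.argwhere(~np.isfinite(self.activity))[0]
            raise ValidationError(
                f"non-finite activity at trial {bad[0]}, voxel {bad[1]}"
            )
        unknown = set(self.trial_split) - set(SPLITS)
        if unknown:
            raise ValidationError(f"unknown split tags {sorted(unknown)}")
        train_cats = set(
            self.trial_category[np.isin(self.trial_split, TRAIN_SPLITS)].tolist()
        )
        test_cats = set(
            self.trial_category[np.isin(self.trial_split, TEST_SPLITS)].tolist()
        )
        overlap = train_cats & test_cats
        if overlap:
            raise ValidationError(
                f"categories shared between train and test splits: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def n_trials(self) -> int:
        return self.activity.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.activity.shape[1]

    @property
    def roi_names(self) -> list:
        """ROI names in first-appearance (hierarchy) order."""
        seen: dict = {}
        for name in self.voxel_roi:
            seen.setdefault(name, None)
        return list(seen)

    def roi_view(self, roi: str) -> ROIView:
        idx = np.flatnonzero(self.voxel_roi == roi)
        if idx.size == 0:
            raise KeyError(f"unknown ROI {roi!r}; have {self.roi_names}")
        return ROIView(roi_name=roi, voxel_indices=tuple(int(i) for i in idx))

    def split_mask(self, split: str) -> np.ndarray:
        if split not in SPLITS:
            raise ValidationError(f"unknown split {split!r}")
        return self.trial_split == split


def roi_matrix(dataset: TrialDataset, roi: str, split: str) -> np.ndarray:
    """Activity of one ROI restricted to one split.

    Rows follow trial order within the split; columns follow the voxel order
    of ``dataset.voxel_roi``. Pure projection: concatenating over the ROI
    partition reconstructs the split's full activity matrix.
    """
    view = dataset.roi_view(roi)
    mask = dataset.split_mask(split)
    if not mask.any():
        raise ValidationError(f"split {split!r} is empty")
    return dataset.activity[np.ix_(mask.nonzero()[0], view.voxel_indices)]


def preprocess_runs(
    run_timeseries: np.ndarray,
    block_onsets: Sequence[int],
    block_length: int,
    shift: int = 0,
) -> np.ndarray:
    """Detrend, percent-normalize and block-average one run of volume data.

    Per voxel: remove the least-squares linear trend over the run, express the
    residual as percent of the run mean (``100·(x − trend)/mean``), then
    average the window ``[onset+shift, onset+shift+block_length)`` for each
    block. Output is invariant to adding any affine trend ``a + b·t``.
    """
    ts = np.asarray(run_timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValidationError("run_timeseries must be (volumes, voxels)")
    n_vol = ts.shape[0]
    onsets = np.asarray(block_onsets, dtype=int)
    if block_length <= 0:
        raise ValidationError("block_length must be positive")
    last = onsets.max(initial=0) + shift + block_length
    if (onsets + shift < 0).any() or last > n_vol:
        raise IndexError(
            f"block window exceeds run bounds (need {last} volumes, have {n_vol})"
        )
    t = np.arange(n_vol, dtype=float)
    design = np.column_stack([np.ones(n_vol), t])
    coef, *_ = np.linalg.lstsq(design, ts, rcond=None)
    resid = ts - design @ coef
    run_mean = ts.mean(axis=0)
    if np.any(run_mean == 0):
        raise ValidationError("zero run mean: percent normalization undefined")
    psc = 100.0 * resid / run_mean
    blocks = np.empty((len(onsets), ts.shape[1]))
    for i, onset in enumerate(onsets):
        lo = onset + shift
        blocks[i] = psc[lo : lo + block_length].mean(axis=0)
    return blocks


def average_by_category(
    matrix: np.ndarray, categories: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of rows sharing a category, rows ordered by ascending category id."""
    matrix = np.asarray(matrix, dtype=float)
    categories = np.asarray(categories, dtype=np.int64)
    if matrix.shape[0] != categories.shape[0]:
        raise ValidationError("row/category length mismatch")
    order = np.unique(categories)
    out = np.empty((order.size, matrix.shape[1]))
    for i, cat in enumerate(order):
        rows = categories == cat
        out[i] = matrix[rows].mean(axis=0)
    return out, order


def average_test_trials(
    dataset: TrialDataset, split: str
) -> tuple[np.ndarray, np.ndarray]:
    """Average repeated test presentations of each category.

    Mirrors the per-category averaging of the repeated test trials (35
    perception / 10 imagery presentations) that boosts the signal-to-noise
    ratio before feature prediction. Returns the averaged matrix (one row per
    category, ascending category id) and the category order.
    """
    if split not in TEST_SPLITS:
        raise ValidationError(f"{split!r} is not a test split")
    mask = dataset.split_mask(split)
    if not mask.any():
        raise ValidationError(f"split {split!r} is empty")
    return average_by_category(
        dataset.activity[mask], dataset.trial_category[mask]
    )


# ---------------------------------------------------------------------------
# Container persistence
# ---------------------------------------------------------------------------

def _is_text_container(path: Path) -> bool:
    return path.is_dir() or path.suffix.lower() in ("", ".d") and not path.exists()


def save_container(
    dataset: TrialDataset,
    features: Sequence[FeatureTable],
    path,
    overwrite: bool = False,
) -> None:
    """Persist a dataset plus feature tables.

    ``path`` ending in ``.h5``/``.hdf5`` writes a single HDF5 file; any other
    path writes a directory of CSV files with the same logical schema.
    Refuses to clobber an existing container unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        _save_hdf5(dataset, features, path)
    else:
        if path.exists() and any(path.iterdir()) and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        _save_text(dataset, features, path)


def load_container(path) -> tuple[TrialDataset, list]:
    """Load a dataset + feature tables written by :func:`save_container`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _load_text(path)
    return _load_hdf5(path)


def _save_hdf5(dataset, features, path: Path) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = dataset.subject_id
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("activity", data=dataset.activity, dtype="f8")
        f.create_dataset("trial_category", data=dataset.trial_category)
        f.create_dataset(
            "trial_split", data=dataset.trial_split.astype(object), dtype=str_dt
        )
        f.create_dataset("trial_run", data=dataset.trial_run)
        f.create_dataset(
            "voxel_roi", data=dataset.voxel_roi.astype(object), dtype=str_dt
        )
        grp = f.create_group("features")
        for table in features:
            g = grp.create_group(table.feature_name)
            g.create_dataset("values", data=table.values, dtype="f8")
            g.create_dataset("category_ids", data=table.category_ids)
            g.create_dataset(
                "unit_ids",
                data=np.asarray([str(u) for u in table.unit_ids], dtype=object),
                dtype=str_dt,
            )


def _require(f, key: str):
    if key not in f:
        raise SchemaError(f"container missing required dataset {key!r}")
    return f[key]


def _load_hdf5(path: Path):
    with h5py.File(path, "r") as f:
        if "subject_id" not in f.attrs:
            raise SchemaError("container missing attribute 'subject_id'")
        dataset = TrialDataset(
            subject_id=str(f.attrs["subject_id"]),
            activity=_require(f, "activity")[...],
            trial_category=_require(f, "trial_category")[...],
            trial_split=[s.decode() if isinstance(s, bytes) else s
                         for s in _require(f, "trial_split")[...]],
            trial_run=_require(f, "trial_run")[...],
            voxel_roi=[s.decode() if isinstance(s, bytes) else s
                       for s in _require(f, "voxel_roi")[...]],
        )
        features = []
        if "features" in f:
            for name in sorted(f["features"]):
                g = f["features"][name]
                features.append(
                    FeatureTable(
                        feature_name=name,
                        values=_require(g, "values")[...],
                        category_ids=_require(g, "category_ids")[...],
                        unit_ids=[
                            u.decode() if isinstance(u, bytes) else u
                            for u in _require(g, "unit_ids")[...]
                        ],
                    )
                )
    return dataset, features


def _save_text(dataset, features, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(dataset.activity).to_csv(path / "activity.csv", index=False)
    pd.DataFrame(
        {
            "trial_category": dataset.trial_category,
            "trial_split": dataset.trial_split,
            "trial_run": dataset.trial_run,
        }
    ).to_csv(path / "trials.csv", index=False)
    pd.DataFrame({"voxel_roi": dataset.voxel_roi}).to_csv(
        path / "voxels.csv", index=False
    )
    with open(path / "meta.csv", "w") as fh:
        fh.write("subject_id,schema_version\n")
        fh.write(f"{dataset.subject_id},{SCHEMA_VERSION}\n")
    for table in features:
        df = pd.DataFrame(table.values, columns=[str(u) for u in table.unit_ids])
        df.insert(0, "category_id", table.category_ids)
        df.to_csv(path / f"features_{table.feature_name}.csv", index=False)


def _load_text(path: Path):
    for required in ("activity.csv", "trials.csv", "voxels.csv", "meta.csv"):
        if not (path / required).exists():
            raise SchemaError(f"container missing file {required!r}")
    meta = pd.read_csv(path / "meta.csv")
    trials = pd.read_csv(path / "trials.csv")
    for col in ("trial_category", "trial_split", "trial_run"):
        if col not in trials.columns:
            raise SchemaError(f"trials.csv missing column {col!r}")
    voxels = pd.read_csv(path / "voxels.csv")
    if "voxel_roi" not in voxels.columns:
        raise SchemaError("voxels.csv missing column 'voxel_roi'")
    dataset = TrialDataset(
        subject_id=str(meta["subject_id"].iloc[0]),
        activity=pd.read_csv(path / "activity.csv").to_numpy(dtype=float),
        trial_category=trials["trial_category"].to_numpy(),
        trial_split=trials["trial_split"].to_numpy(),
        trial_run=trials["trial_run"].to_numpy(),
        voxel_roi=voxels["voxel_roi"].to_numpy(),
    )
    features = []
    for fpath in sorted(path.glob("features_*.csv")):
        name = fpath.stem[len("features_"):]
        df = pd.read_csv(fpath)
        if "category_id" not in df.columns:
            raise SchemaError(f"{fpath.name} missing column 'category_id'")
        features.append(
            FeatureTable(
                feature_name=name,
                values=df.drop(columns="category_id").to_numpy(dtype=float),
                category_ids=df["category_id"].to_numpy(),
                unit_ids=list(df.columns[1:]),
            )
        )
    return dataset, features
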
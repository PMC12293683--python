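"""Subject x ROI volume tables: loading, validation, normalisation and splits.

The tabular entry point of the pipeline. A cohort is a table with one row per
subject carrying chronological age, total intracranial volume (TIV) and, for
each of N atlas regions (ROIs), a grey-matter and a white-matter volume
column. Columns are named ``<ROI>_GM`` and ``<ROI>_WM``; the delimiter is
inferred from the file extension (``.tsv`` -> tab, otherwise comma).

Processing order is enforced through state flags: volumes are first divided
by the subject's TIV (head-size correction), then each ROI column is brought
to zero mean / unit variance with statistics fitted on a reference (normally
the training) split. Sample standard deviation (ddof=1) is used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROIVolumeTable",
    "StandardizationParams",
    "load_volume_table",
    "save_volume_table",
    "normalize_by_tiv",
    "fit_standardizer",
    "apply_standardizer",
    "unapply_standardizer",
    "split_holdout",
    "make_folds",
]

ID_COL = "subject_id"
AGE_COL = "age"
TIV_COL = "tiv"


class SchemaError(ValueError):
    """A required column is absent or malformed."""


class StateError(RuntimeError):
    """An operation was applied in the wrong processing state."""


@dataclass(frozen=True)
class ROIVolumeTable:
    """In-memory cohort: GM/WM volume matrices plus per-subject covariates.

    ``gm`` and ``wm`` are M x N float arrays (subjects x ROIs), ``ages`` and
    ``tiv`` length-M vectors, ``roi_names`` the N region labels. The two
    boolean flags record whether TIV normalisation and per-ROI
    standardisation have been applied, in that order.
    """

    subject_ids: tuple
    ages: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    tiv: np.ndarray | None
    roi_names: tuple
    normalized: bool = False
    standardized: bool = False

    def __post_init__(self):
        m, n = self.gm.shape
        if self.wm.shape != (m, n):
            raise SchemaError(
                f"gm shape {self.gm.shape} != wm shape {self.wm.shape}"
            )
        if len(self.ages) != m or len(self.subject_ids) != m:
            raise SchemaError("ages/subject_ids length does not match gm rows")
        if len(self.roi_names) != n:
            raise SchemaError("roi_names length does not match gm columns")
        for name, arr in (("gm", self.gm), ("wm", self.wm), ("ages", self.ages)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.ages <= 0):
            raise ValueError("ages must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return self.gm.shape[0]

    @property
    def n_rois(self) -> int:
        return self.gm.shape[1]

    def take(self, idx) -> "ROIVolumeTable":
        """Row subset preserving processing state."""
        idx = np.asarray(idx)
        return replace(
            self,
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            ages=self.ages[idx],
            gm=self.gm[idx],
            wm=self.wm[idx],
            tiv=None if self.tiv is None else self.tiv[idx],
        )

    def node_features(self) -> np.ndarray:
        """Per-subject N x 2 node feature tensor (GM, WM), shape (M, N, 2)."""
        return np.stack([self.gm, self.wm], axis=-1)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-ROI mean/SD of GM and WM, fitted on a reference table."""

    roi_names: tuple
    gm_mean: np.ndarray
    gm_sd: np.ndarray
    wm_mean: np.ndarray
    wm_sd: np.ndarray

    def __post_init__(self):
        n = len(self.roi_names)
        for arr in (self.gm_mean, self.gm_sd, self.wm_mean, self.wm_sd):
            if len(arr) != n:
                raise SchemaError("standardizer length does not match roi_names")
        if np.any(self.gm_sd <= 0) or np.any(self.wm_sd <= 0):
            raise ValueError("standard deviations must be strictly positive")

    def to_json(self, path):
        payload = {
            roi: {
                "gm_mean": float(self.gm_mean[i]),
                "gm_sd": float(self.gm_sd[i]),
                "wm_mean": float(self.wm_mean[i]),
                "wm_sd": float(self.wm_sd[i]),
            }
            for i, roi in enumerate(self.roi_names)
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "StandardizationParams":
        payload = json.loads(Path(path).read_text())
        rois = tuple(payload)
        get = lambda k: np.array([payload[r][k] for r in rois], dtype=float)
        return cls(rois, get("gm_mean"), get("gm_sd"), get("wm_mean"), get("wm_sd"))


def _delimiter(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def load_volume_table(path) -> ROIVolumeTable:
    """Read a cohort CSV/TSV into a validated :class:`ROIVolumeTable`.

    Required columns: ``subject_id``, ``age``, ``tiv`` and matched
    ``<ROI>_GM`` / ``<ROI>_WM`` pairs. Row order is preserved. Raises
    :class:`SchemaError` naming any missing column and ``ValueError`` with
    row/column coordinates for non-numeric cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter(path), float_precision="round_trip")
    for col in (ID_COL, AGE_COL, TIV_COL):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    gm_cols = [c for c in df.columns if c.endswith("_GM")]
    wm_cols = [c for c in df.columns if c.endswith("_WM")]
    rois = [c[:-3] for c in gm_cols]
    if not rois:
        raise SchemaError("no <ROI>_GM columns found")
    if [c[:-3] for c in wm_cols] != rois:
        raise SchemaError(
            "GM and WM columns do not name the same ROIs in the same order; "
            "the model requires both features per ROI"
        )
    numeric = df[[AGE_COL, TIV_COL] + gm_cols + wm_cols].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna() & df[numeric.columns].notna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        isna = numeric.isna().to_numpy()
        r, c = np.argwhere(isna)[0]
        raise ValueError(
            f"non-numeric or missing value at row {r}, column {numeric.columns[c]!r}"
        )
    return ROIVolumeTable(
        subject_ids=tuple(df[ID_COL].astype(str)),
        ages=numeric[AGE_COL].to_numpy(float),
        gm=numeric[gm_cols].to_numpy(float),
        wm=numeric[wm_cols].to_numpy(float),
        tiv=numeric[TIV_COL].to_numpy(float),
        roi_names=tuple(rois),
    )


def save_volume_table(table: ROIVolumeTable, path) -> None:
    """Write a table in the dialect :func:`load_volume_table` reads."""
    df = pd.DataFrame({ID_COL: table.subject_ids, AGE_COL: table.ages})
    df[TIV_COL] = table.tiv if table.tiv is not None else np.nan
    for j, roi in enumerate(table.roi_names):
        df[f"{roi}_GM"] = table.gm[:, j]
    for j, roi in enumerate(table.roi_names):
        df[f"{roi}_WM"] = table.wm[:, j]
    df.to_csv(path, sep=_delimiter(path), index=False)


def normalize_by_tiv(table: ROIVolumeTable) -> ROIVolumeTable:
    """Divide each subject's GM/WM volumes by their intracranial volume."""
    if table.normalized:
        raise StateError("table is already TIV-normalized")
    if table.tiv is None:
        raise StateError("table has no TIV column")
    if np.any(table.tiv <= 0):
        bad = table.subject_ids[int(np.argmax(table.tiv <= 0))]
        raise ValueError(f"non-positive TIV for subject {bad!r}")
    scale = table.tiv[:, None]
    return replace(table, gm=table.gm / scale, wm=table.wm / scale, normalized=True)


def fit_standardizer(table: ROIVolumeTable) -> StandardizationParams:
    """Per-ROI mean and sample SD (ddof=1) of GM and WM across subjects."""
    if not table.normalized:
        raise StateError("fit the standardizer on a TIV-normalized table")
    if table.n_subjects < 2:
        raise ValueError("need at least 2 subjects to estimate an SD")
    gm_sd = table.gm.std(axis=0, ddof=1)
    wm_sd = table.wm.std(axis=0, ddof=1)
    for sd, kind in ((gm_sd, "GM"), (wm_sd, "WM")):
        if np.any(sd == 0):
            roi = table.roi_names[int(np.argmax(sd == 0))]
            raise ValueError(f"zero variance in {kind} column for ROI {roi!r}")
    return StandardizationParams(
        table.roi_names,
        table.gm.mean(axis=0),
        gm_sd,
        table.wm.mean(axis=0),
        wm_sd,
    )


def apply_standardizer(
    table: ROIVolumeTable, params: StandardizationParams
) -> ROIVolumeTable:
    """Centre and scale each ROI column: (x - mean) / SD, GM and WM."""
    if not table.normalized:
        raise StateError("standardize only TIV-normalized tables")
    if table.standardized:
        raise StateError("table is already standardized")
    if params.roi_names != table.roi_names:
        raise SchemaError("standardizer ROI names do not match the table")
    return replace(
        table,
        gm=(table.gm - params.gm_mean) / params.gm_sd,
        wm=(table.wm - params.wm_mean) / params.wm_sd,
        standardized=True,
    )


def unapply_standardizer(
    table: ROIVolumeTable, params: StandardizationParams
) -> ROIVolumeTable:
    """Inverse of :func:`apply_standardizer` (x * SD + mean)."""
    if not table.standardized:
        raise StateError("table is not standardized")
    return replace(
        table,
        gm=table.gm * params.gm_sd + params.gm_mean,
        wm=table.wm * params.wm_sd + params.wm_mean,
        standardized=False,
    )


def split_holdout(table: ROIVolumeTable, test_fraction: float, seed: int):
    """Disjoint, exhaustive train/test partition.

    The test set gets ``floor(M * test_fraction)`` subjects (remainder to
    train); the shuffle is a pure function of ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    m = table.n_subjects
    n_test = int(np.floor(m * test_fraction))
    perm = np.random.default_rng(seed).permutation(m)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return table.take(train_idx), table.take(test_idx)


def make_folds(table: ROIVolumeTable, k: int, seed: int) -> np.ndarray:
    """Fold label in {0..k-1} per subject; sizes differ by at most one."""
    m = table.n_subjects
    if not 2 <= k <= m:
        raise ValueError(f"k must be in [2, {m}], got {k}")
    perm = np.random.default_rng(seed).permutation(m)
    labels = np.empty(m, dtype=int)
    # first (m % k) folds get the extra subject
    sizes = np.full(k, m // k)
    sizes[: m % k] += 1
    start = 0
    for f, size in enumerate(sizes):
        labels[perm[start : start + size]] = f
        start += size
    return labels
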
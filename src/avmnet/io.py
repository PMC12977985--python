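"""Readers and writers for all on-disk formats.

Connectivity matrices travel as tab-separated text with an optional single
header row of parcel ids; NIfTI-1 volumes carry label grids and lesion masks;
cohort and cognition tables are CSV; analysis results are JSON plus TSV tables.
Inputs must already be co-registered — nothing here resamples.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    AlignmentError,
    ConnectivityMatrix,
    DimensionError,
    MatrixFormatError,
    ParcelAtlas,
    SubjectRecord,
)

logger = logging.getLogger("avmnet")

SYMMETRY_TOL = 1e-8


# ---------------------------------------------------------------------------
# connectivity matrices (TSV)
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    atlas: ParcelAtlas,
    modality: str,
    valid: np.ndarray | None = None,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Read an N x N connectivity matrix from TSV in atlas order.

    A first row of integers matching the parcel count is treated as a header
    of parcel ids. The matrix is symmetrized by averaging when the asymmetry
    is within 1e-8, the diagonal is forced to zero, and all nodes are valid
    unless a ``valid`` mask is supplied (missingness never travels as NaN).
    """
    n = atlas.n_parcels
    raw = pd.read_csv(path, sep="\t", header=None)
    if raw.shape[0] == raw.shape[1] + 1:
        first = raw.iloc[0].to_numpy()
        if np.all(first == np.round(first)):
            raw = raw.iloc[1:]
    mat = raw.to_numpy(dtype=float)
    if mat.shape != (n, n):
        raise DimensionError(
            f"matrix shape {mat.shape} does not match {n}-parcel atlas"
        )
    if np.any(np.isnan(mat)):
        raise MatrixFormatError(
            "NaN cell in matrix file; missingness must come via a valid mask"
        )
    asym = np.max(np.abs(mat - mat.T))
    if asym > SYMMETRY_TOL:
        raise MatrixFormatError(f"asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}")
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return ConnectivityMatrix(weights=mat, modality=modality, valid=valid, subject_id=subject_id)


def write_matrix(mat: ConnectivityMatrix, path: str | Path, atlas: ParcelAtlas | None = None) -> None:
    """Write a connectivity matrix as TSV with a parcel-id header row."""
    n = mat.n_nodes
    ids = atlas.parcel_ids if atlas is not None else np.arange(1, n + 1)
    with open(path, "w") as fh:
        fh.write("\t".join(str(int(i)) for i in ids) + "\n")
        for row in mat.weights:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_label_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an integer parcel-label volume; returns (grid, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = np.rint(data).astype(int)
    return grid, img.affine


def read_lesion_mask(path: str | Path, labels: np.ndarray | None = None,
                     label_affine: np.ndarray | None = None) -> np.ndarray:
    """Read a lesion mask (binarized at > 0), optionally checking alignment.

    When a label grid (and optionally its affine) is supplied, shape and
    affine must match exactly — inputs are expected pre-registered.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    mask = data > 0
    if labels is not None and mask.shape != labels.shape:
        raise AlignmentError(
            f"lesion mask shape {mask.shape} != label volume shape {labels.shape}"
        )
    if label_affine is not None and not np.allclose(img.affine, label_affine, atol=1e-6):
        raise AlignmentError("lesion mask affine differs from label volume affine")
    return mask


def write_volume(grid: np.ndarray, path: str | Path, voxel_size: float = 2.0) -> None:
    """Write a 3-D grid as NIfTI-1 with an isotropic diagonal affine."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    arr = np.asarray(grid)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_atlas(path: str | Path) -> ParcelAtlas:
    """Read a parcel lookup table (CSV) into a ParcelAtlas (no label volume)."""
    return ParcelAtlas(table=pd.read_csv(path))


def write_atlas(atlas: ParcelAtlas, path: str | Path) -> None:
    atlas.table.to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read the per-subject cohort table (CSV) into SubjectRecords."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        sm = row.get("sm_grade")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                mFD=float(row.get("mFD", 0.0)),
                TIV=float(row.get("TIV", 0.0)),
                seizure=bool(row.get("seizure", False)),
                sm_grade=None if pd.isna(sm) else int(sm),
            )
        )
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "education": [r.education for r in records],
            "mFD": [r.mFD for r in records],
            "TIV": [r.TIV for r in records],
            "seizure": [r.seizure for r in records],
            "sm_grade": [r.sm_grade for r in records],
        }
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _jsonify(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return {c: _jsonify(obj[c].to_numpy()) for c in obj.columns}
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise TypeError(f"unserializable object of type {type(obj).__name__}")


def write_report(results: Mapping[str, Any], path: str | Path) -> None:
    """Write a nested result mapping as JSON with deterministic key order.

    Floats are serialized at full double precision, so write-then-read
    round-trips losslessly (well under 1e-12).
    """
    payload = _jsonify(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy result table as TSV (no index)."""
    df.to_csv(path, sep="\t", index=False)
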
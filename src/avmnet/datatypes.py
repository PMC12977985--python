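"""Shared data model for lesion-aware connectome analysis.

Nodes are cortical parcels of a fixed atlas (the 360-parcel HCP-MMP1 grid in
the clinical setting; smaller synthetic atlases in simulation). Connectivity is
carried as dense symmetric matrices with an explicit node-validity mask:
missingness never travels as NaN inside the weights, which keeps all graph code
branch-free. Node order is atlas order everywhere; files are never reordered on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R")

#: Canonical functional systems used by the synthetic atlas. Real atlases may
#: use any label set; the network column is configuration, not ground truth.
CANONICAL_NETWORKS = ("Visual", "Somatomotor", "DAN", "VAN", "Limbic", "FPN", "DMN")


class AvmnetError(Exception):
    """Base class for package errors."""


class DimensionError(AvmnetError, ValueError):
    """Array shape does not match the atlas."""


class MatrixFormatError(AvmnetError, ValueError):
    """On-disk matrix violates the format contract (NaN, asymmetry, ...)."""


class AlignmentError(AvmnetError, ValueError):
    """Paired volumes do not share shape/affine."""


class DegenerateInputError(AvmnetError, ValueError):
    """Input is structurally valid but leaves nothing to analyze."""


@dataclass
class ParcelAtlas:
    """Parcel lookup table, optionally with a voxel label volume.

    ``table`` columns: parcel_id (1..N, unique, ascending), name, hemisphere
    (L/R), network (categorical label), node_volume (positive voxel count or
    mm^3). ``label_volume`` is a 3-D integer grid whose voxel values are parcel
    ids (0 = background); ``voxel_size`` its isotropic edge length in mm.
    """

    table: pd.DataFrame
    label_volume: np.ndarray | None = None
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        required = {"parcel_id", "name", "hemisphere", "network", "node_volume"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        pid = np.asarray(self.table["parcel_id"], dtype=int)
        if len(np.unique(pid)) != len(pid):
            raise ValueError("parcel_ids must be unique")
        if not np.array_equal(pid, np.arange(1, len(pid) + 1)):
            raise ValueError("parcel_ids must be contiguous 1..N in table order")
        vol = np.asarray(self.table["node_volume"], dtype=float)
        if np.any(vol <= 0):
            raise ValueError("node_volume must be positive for every parcel")
        bad_hemi = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        if self.label_volume is not None:
            labels = np.unique(self.label_volume)
            unknown = set(labels[labels != 0].tolist()) - set(pid.tolist())
            if unknown:
                raise ValueError(f"label volume contains unknown parcel ids: {sorted(unknown)}")

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.asarray(self.table["parcel_id"], dtype=int)

    @property
    def node_volumes(self) -> np.ndarray:
        return np.asarray(self.table["node_volume"], dtype=float)

    @property
    def networks(self) -> np.ndarray:
        return np.asarray(self.table["network"], dtype=object)

    def parcels_in_network(self, network: str) -> np.ndarray:
        """Parcel ids assigned to ``network`` (raises on unknown label)."""
        known = set(self.networks.tolist())
        if network not in known:
            raise ValueError(f"unknown network label {network!r}; known: {sorted(known)}")
        return self.parcel_ids[self.networks == network]

    def index_of(self, parcel_ids: Sequence[int] | np.ndarray) -> np.ndarray:
        """0-based row indices of the given parcel ids."""
        ids = np.atleast_1d(np.asarray(parcel_ids, dtype=int))
        bad = set(ids.tolist()) - set(self.parcel_ids.tolist())
        if bad:
            raise IndexError(f"unknown parcel ids: {sorted(bad)}")
        return ids - 1


@dataclass
class ConnectivityMatrix:
    """Square symmetric weighted connectivity over atlas parcels.

    ``valid`` marks analyzable nodes; rows/columns of invalid nodes are
    ignored by every downstream metric rather than treated as zeros.
    """

    weights: np.ndarray
    modality: str  # "SC" or "FC"
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != n:
            raise DimensionError(f"weights must be square, got {self.weights.shape}")
        if self.modality not in ("SC", "FC"):
            raise ValueError(f"modality must be 'SC' or 'FC', got {self.modality!r}")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (n,):
            raise DimensionError("valid mask length must match matrix size")
        sub = self.weights[np.ix_(self.valid, self.valid)]
        if np.any(~np.isfinite(sub)):
            raise MatrixFormatError("non-finite weight among valid nodes")
        if not np.allclose(sub, sub.T, atol=1e-8, rtol=0.0):
            raise MatrixFormatError("weights not symmetric on valid nodes")
        if np.any(np.abs(np.diag(self.weights)[self.valid]) > 0):
            raise MatrixFormatError("diagonal must be zero")
        if self.modality == "SC" and np.any(sub < 0):
            raise MatrixFormatError("SC weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_submatrix(self) -> np.ndarray:
        return self.weights[np.ix_(self.valid, self.valid)]

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            weights=self.weights.copy(),
            modality=self.modality,
            valid=self.valid.copy(),
            subject_id=self.subject_id,
        )


@dataclass
class RegionalLesionProfile:
    """Per-parcel lesion overlap fractions plus whole-brain lesion load."""

    proportion: np.ndarray  # length N, in [0, 1]; NaN = parcel absent from labels
    total_lesion_load: float  # lesioned voxels / TIV voxels
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.proportion = np.asarray(self.proportion, dtype=float)
        finite = self.proportion[np.isfinite(self.proportion)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValueError("lesion proportions must lie in [0, 1]")
        if self.total_lesion_load < 0:
            raise ValueError("total lesion load must be nonnegative")


@dataclass
class SubjectRecord:
    """Demographic/clinical covariates for one participant."""

    subject_id: str
    group: str  # "AVM" or "NC"
    age: float
    sex: str  # "M" or "F"
    education: float
    mFD: float = 0.0
    TIV: float = 0.0
    seizure: bool = False
    sm_grade: int | None = None

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group must be nonempty")
        for name in ("age", "education", "mFD", "TIV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass
class CognitiveBattery:
    """Raw neuropsychological scores with latency flags and domain membership.

    ``scores``: subjects x tests DataFrame (index = subject_id).
    ``latency_flags``: test -> True when the raw metric is a latency
    (lower = better), so its z-score is negated after standardization.
    ``domain_map``: domain -> member tests; a test may serve several domains
    (Verbal Fluency counts toward both Executive and Language).
    """

    scores: pd.DataFrame
    latency_flags: Mapping[str, bool]
    domain_map: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        for domain, tests in self.domain_map.items():
            for t in tests:
                if t not in self.latency_flags:
                    raise ValueError(f"test {t!r} in domain {domain!r} has no latency flag")
                if t not in self.scores.columns:
                    raise ValueError(f"test {t!r} in domain {domain!r} missing from scores")
        if "Global" in self.domain_map:
            if set(self.domain_map["Global"]) != {"MMSE", "MoCA"}:
                raise ValueError("Global domain must be exactly {MMSE, MoCA}")


@dataclass
class AtrophyMap:
    """Per-parcel group-difference t-statistics for a morphometry metric.

    Positive values follow ``sign_convention`` (default: patient > control,
    i.e., thickening positive as in a cohort with predominant remodeling).
    """

    tstat: np.ndarray
    metric: str = "thickness"
    sign_convention: str = "patient_minus_control"

    def __post_init__(self) -> None:
        self.tstat = np.asarray(self.tstat, dtype=float)
        if self.tstat.ndim != 1:
            raise DimensionError("tstat must be a vector")
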
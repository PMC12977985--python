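"""Construction of analysis-ready structural and functional networks.

FC comes from Pearson correlation of parcel BOLD time series; SC from
streamline counts normalized by the inverse sum of endpoint node volumes to
remove parcel-size bias. Parcels overlapping the lesion by >= 50% (the
default cutoff) are excluded from the node set, and topology metrics operate
on proportionally thresholded graphs (keeping the top ``density`` fraction
of edges). Negative FC edges are zeroed before thresholding so weights stay
interpretable as connection strengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    ConnectivityMatrix,
    DegenerateInputError,
    DimensionError,
    RegionalLesionProfile,
)

logger = logging.getLogger("avmnet")


@dataclass
class TimeSeriesSet:
    """Denoised BOLD time series: T time points x N parcels."""

    data: np.ndarray
    subject_id: str = ""
    mFD: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 3:
            raise ValueError("time series must be T x N with T >= 3")


def build_fc(ts: TimeSeriesSet) -> ConnectivityMatrix:
    """Pearson-correlation FC; zero-variance parcels are marked invalid."""
    X = ts.data
    n = X.shape[1]
    var = X.var(axis=0)
    valid = var > 0
    fc = np.zeros((n, n))
    if valid.sum() >= 2:
        sub = np.corrcoef(X[:, valid], rowvar=False)
        fc[np.ix_(valid, valid)] = sub
    np.fill_diagonal(fc, 0.0)
    fc[~valid, :] = 0.0
    fc[:, ~valid] = 0.0
    if np.any(~valid):
        logger.info("build_fc: %d zero-variance parcels marked invalid", int((~valid).sum()))
    return ConnectivityMatrix(weights=fc, modality="FC", valid=valid, subject_id=ts.subject_id)


def normalize_sc_invnodevol(raw_counts: np.ndarray, node_volumes: np.ndarray,
                            subject_id: str = "") -> ConnectivityMatrix:
    """invnodevol normalization: SC[i,j] = counts[i,j] / (vol_i + vol_j)."""
    counts = np.asarray(raw_counts, dtype=float)
    vols = np.asarray(node_volumes, dtype=float)
    if counts.shape != (len(vols), len(vols)):
        raise DimensionError("count matrix shape must match node volume vector")
    if np.any(counts < 0):
        raise ValueError("streamline counts must be nonnegative")
    if np.any(vols <= 0):
        raise ValueError("node volumes must be positive")
    denom = vols[:, None] + vols[None, :]
    sc = counts / denom
    np.fill_diagonal(sc, 0.0)
    return ConnectivityMatrix(weights=sc, modality="SC", subject_id=subject_id)


def apply_lesion_mask(
    mat: ConnectivityMatrix,
    lesions: RegionalLesionProfile,
    cutoff: float = 0.5,
) -> ConnectivityMatrix:
    """Exclude nodes whose lesion overlap proportion is >= ``cutoff``.

    The boundary is inclusive (a parcel exactly half lesioned is excluded).
    Excluded nodes stay in the matrix but are flagged invalid, so all
    downstream metrics ignore them.
    """
    prop = np.asarray(lesions.proportion, dtype=float)
    if prop.shape[0] != mat.n_nodes:
        raise DimensionError("lesion profile length must match matrix size")
    out = mat.copy()
    excluded = np.zeros(mat.n_nodes, dtype=bool)
    finite = np.isfinite(prop)
    excluded[finite] = prop[finite] >= cutoff
    out.valid = out.valid & ~excluded
    if not np.any(out.valid):
        raise DegenerateInputError("lesion masking removed every node: empty network")
    n_exc = int(excluded.sum())
    if n_exc:
        logger.info("apply_lesion_mask: excluded %d nodes at cutoff %.2f", n_exc, cutoff)
    return out


def proportional_threshold(mat: ConnectivityMatrix, density: float) -> ConnectivityMatrix:
    """Keep the ceil(density * M) strongest upper-triangle edges over valid nodes.

    For FC inputs, negative edges are zeroed first (they never count toward
    the retained set). Edges tied at the cutoff weight break deterministically
    to the lexicographically smaller (i, j) pair. Thresholding at a fixed
    density is idempotent.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    out = mat.copy()
    if out.modality == "FC":
        out.weights[out.weights < 0] = 0.0
    vidx = np.flatnonzero(out.valid)
    nv = len(vidx)
    if nv < 2:
        return out
    iu, ju = np.triu_indices(nv, k=1)
    w = out.weights[vidx[iu], vidx[ju]]
    m_possible = len(w)
    keep_k = math.ceil(density * m_possible)
    # order: descending weight, then ascending (i, j)
    order = np.lexsort((ju, iu, -w))
    kept = order[:keep_k]
    new_sub = np.zeros((nv, nv))
    new_sub[iu[kept], ju[kept]] = w[kept]
    new_sub += new_sub.T
    out.weights[np.ix_(vidx, vidx)] = new_sub
    return out
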
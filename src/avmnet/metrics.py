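"""Weighted graph topology metrics and virtual-lesion resilience.

Edge weights are connection strengths, so path lengths use the reciprocal
1/w; global efficiency is the mean inverse shortest-path distance over node
pairs with disconnected pairs contributing zero (the Latora-Marchiori
convention, which keeps the measure finite when a cut vertex is removed).
Weighted clustering uses the Onnela geometric-mean form. Virtual lesion of a
target node compares its efficiency drop against a null of single random
node removals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .datatypes import ConnectivityMatrix, DegenerateInputError

logger = logging.getLogger("avmnet")


@dataclass
class VirtualLesionResult:
    """Efficiency impact of removing one node vs a random-removal null."""

    target_node: int  # parcel id
    E_base: float
    E_removed: float
    delta_pct: float  # 100 * (E_base - E_removed) / E_base
    null_deltas: np.ndarray
    p_value: float  # one-sided, add-one corrected
    n_null: int


def _efficiency_from_adjacency(A: np.ndarray) -> float:
    """Global efficiency of a dense nonnegative adjacency (valid nodes only)."""
    n = A.shape[0]
    if n < 2:
        raise DegenerateInputError("global efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, 1.0 / A, 0.0)
    d = shortest_path(lengths, method="D", directed=False, unweighted=False)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(mat: ConnectivityMatrix) -> float:
    """Mean inverse shortest-path distance over ordered pairs of valid nodes."""
    return _efficiency_from_adjacency(mat.valid_submatrix())


def clustering_coefficient(mat: ConnectivityMatrix, density: float | None = None,
                           return_nodal: bool = False):
    """Onnela weighted clustering, averaged over nodes of degree >= 2.

    C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_jh w'_hi)^(1/3) with
    weights rescaled by the network maximum. Nodes with fewer than two
    neighbors have no triangles and carry C_i = 0. When ``density`` is given
    the matrix is proportionally thresholded first.
    """
    from .network import proportional_threshold

    if density is not None:
        mat = proportional_threshold(mat, density)
    A = mat.valid_submatrix()
    n = A.shape[0]
    if n == 0 or A.max() <= 0:
        logger.warning("clustering_coefficient: empty graph, returning 0")
        return (0.0, np.zeros(n)) if return_nodal else 0.0
    W = (A / A.max()) ** (1.0 / 3.0)
    k = (A > 0).sum(axis=1)
    cyc = np.diag(W @ W @ W)  # 2x the weighted triangle count per node
    C = np.zeros(n)
    deg_ok = k >= 2
    C[deg_ok] = cyc[deg_ok] / (k[deg_ok] * (k[deg_ok] - 1))
    mean_c = float(C[deg_ok].mean()) if np.any(deg_ok) else 0.0
    return (mean_c, C) if return_nodal else mean_c


def node_strength(mat: ConnectivityMatrix) -> np.ndarray:
    """Strength (weighted degree) per node; NaN for invalid nodes."""
    s = np.full(mat.n_nodes, np.nan)
    vidx = np.flatnonzero(mat.valid)
    s[vidx] = mat.valid_submatrix().sum(axis=1)
    return s


def node_strength_rank(mat: ConnectivityMatrix, by: str = "strength"):
    """Rank valid nodes by strength (or degree), 1 = strongest.

    Ties break to the lower parcel id so ranks are a permutation of
    1..n_valid; a ``tied`` flag reports whether any tie occurred.

    Returns (rank vector over all nodes with 0 for invalid, tied flag).
    """
    vidx = np.flatnonzero(mat.valid)
    if len(vidx) < 1:
        raise DegenerateInputError("no valid nodes to rank")
    sub = mat.valid_submatrix()
    if by == "strength":
        score = sub.sum(axis=1)
    elif by == "degree":
        score = (sub > 0).sum(axis=1).astype(float)
    else:
        raise ValueError("by must be 'strength' or 'degree'")
    order = np.lexsort((vidx, -score))
    ranks = np.zeros(mat.n_nodes, dtype=int)
    ranks[vidx[order]] = np.arange(1, len(vidx) + 1)
    tied = bool(len(np.unique(score)) < len(score))
    return ranks, tied


def virtual_lesion(
    mat: ConnectivityMatrix,
    target_node: int,
    n_null: int = 1000,
    rng: np.random.Generator | None = None,
) -> VirtualLesionResult:
    """Remove the target parcel and compare the efficiency drop with a
    null of ``n_null`` uniform single-node random removals (target excluded).

    One-sided p with add-one correction: p = (1 + #{null >= observed}) /
    (n_null + 1), so p is never exactly 0.
    """
    rng = rng or np.random.default_rng()
    target_idx = target_node - 1
    if target_idx < 0 or target_idx >= mat.n_nodes or not mat.valid[target_idx]:
        raise IndexError(f"target parcel {target_node} is not a valid node")
    vidx = np.flatnonzero(mat.valid)
    if len(vidx) < 3:
        raise DegenerateInputError("virtual lesion needs at least 3 valid nodes")
    A = mat.valid_submatrix()
    e_base = _efficiency_from_adjacency(A)
    pos = int(np.flatnonzero(vidx == target_idx)[0])

    def removed_eff(p: int) -> float:
        keep = np.ones(len(vidx), dtype=bool)
        keep[p] = False
        return _efficiency_from_adjacency(A[np.ix_(keep, keep)])

    e_removed = removed_eff(pos)
    obs_delta = 100.0 * (e_base - e_removed) / e_base if e_base > 0 else 0.0
    candidates = np.delete(np.arange(len(vidx)), pos)
    draws = rng.choice(candidates, size=n_null, replace=True)
    null = np.empty(n_null)
    cache: dict[int, float] = {}
    for i, p in enumerate(draws):
        p = int(p)
        if p not in cache:
            e = removed_eff(p)
            cache[p] = 100.0 * (e_base - e) / e_base if e_base > 0 else 0.0
        null[i] = cache[p]
    p_value = (1.0 + np.sum(null >= obs_delta - 1e-12)) / (n_null + 1.0)
    return VirtualLesionResult(
        target_node=target_node,
        E_base=e_base,
        E_removed=e_removed,
        delta_pct=obs_delta,
        null_deltas=null,
        p_value=float(p_value),
        n_null=n_null,
    )
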
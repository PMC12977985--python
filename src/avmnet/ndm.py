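"""Network Diffusion Model: heat-kernel spread on the structural connectome.

Pathology seeded at a single region x0 spreads along white-matter connections
according to dx/dt = -beta * L x, i.e. x(t) = exp(-beta*L*t) x0, with L the
symmetric normalized graph Laplacian of the structural network. Sweeping every
cortical region as seed and correlating the simulated pattern with an
empirical morphometry t-map identifies the "epicenter": the seed whose
diffusion pattern best matches the observed deformation.

Only the product beta*t is identifiable (the kernel depends on beta and t
solely through beta*t), so beta defaults to 1 and t is swept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import AtrophyMap, ConnectivityMatrix, DegenerateInputError, DimensionError


@dataclass
class DiffusionSpec:
    """Parameters of the diffusion sweep.

    beta: diffusion constant (1/time); fixed at 1 by default since only
    beta*t matters. t_grid: strictly increasing diffusion times, default
    0..10 in steps of 0.05. laplacian_kind: 'sym_normalized' (default) or
    'random_walk'.
    """

    beta: float = 1.0
    t_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 10.0 + 1e-9, 0.05))
    laplacian_kind: str = "sym_normalized"

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.t_grid.ndim != 1 or len(self.t_grid) == 0:
            raise ValueError("t_grid must be a nonempty vector")
        if np.any(np.diff(self.t_grid) <= 0) or self.t_grid[0] < 0:
            raise ValueError("t_grid must be strictly increasing and start >= 0")
        if self.laplacian_kind not in ("sym_normalized", "random_walk"):
            raise ValueError(f"unknown laplacian_kind {self.laplacian_kind!r}")


@dataclass
class NDMResult:
    """Epicenter sweep output.

    r_matrix: seeds x times Pearson correlations with the empirical map
    (rows follow ``seed_parcels``). ranking: parcel ids of valid seeds in
    descending order of peak r (ties to the lower parcel id). ``epicenter``
    is ranking[0]; ``t_opt``/``r_max`` locate the global maximum.
    """

    seed_parcels: np.ndarray
    t_grid: np.ndarray
    r_matrix: np.ndarray
    peak_r: np.ndarray
    peak_t: np.ndarray
    ranking: np.ndarray
    epicenter: int
    t_opt: float
    r_max: float


def normalized_laplacian(sc: ConnectivityMatrix | np.ndarray, kind: str = "sym_normalized") -> np.ndarray:
    """Normalized graph Laplacian of the valid-node structural submatrix.

    sym_normalized: L = I - D^{-1/2} A D^{-1/2} (symmetric, eigenvalues in
    [0, 2]). random_walk: L = I - D^{-1} A. Isolated nodes (degree 0) get a
    zero row/column so they neither emit nor absorb signal.
    """
    A = sc.valid_submatrix() if isinstance(sc, ConnectivityMatrix) else np.asarray(sc, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    deg = A.sum(axis=1)
    if np.all(deg == 0):
        raise DegenerateInputError("all-zero adjacency: no edges to diffuse along")
    nz = deg > 0
    n = A.shape[0]
    L = np.zeros((n, n))
    if kind == "sym_normalized":
        dinv_sqrt = np.zeros(n)
        dinv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
        L[np.ix_(nz, nz)] = -A[np.ix_(nz, nz)] * np.outer(dinv_sqrt[nz], dinv_sqrt[nz])
        L[nz, nz] += 1.0
    elif kind == "random_walk":
        dinv = np.zeros(n)
        dinv[nz] = 1.0 / deg[nz]
        L[np.ix_(nz, nz)] = -A[np.ix_(nz, nz)] * dinv[nz][:, None]
        L[nz, nz] += 1.0
    else:
        raise ValueError(f"unknown laplacian kind {kind!r}")
    return L


def diffuse(L: np.ndarray, x0: np.ndarray, beta: float = 1.0, t: float = 0.0) -> np.ndarray:
    """Evaluate x(t) = exp(-beta*L*t) x0 via eigendecomposition of symmetric L."""
    L = np.asarray(L, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape[0] != L.shape[0]:
        raise DimensionError("x0 length must match Laplacian size")
    if t < 0:
        raise ValueError("t must be nonnegative")
    if np.max(np.abs(L - L.T)) > 1e-10:
        raise ValueError("Laplacian must be symmetric for eigendecomposition")
    if t == 0:
        return x0.copy()
    evals, evecs = np.linalg.eigh(L)
    # group beta*t so the kernel depends on the product alone, bit-for-bit
    return (evecs * np.exp(-(beta * t) * evals)) @ (evecs.T @ x0)


def heat_kernels(L: np.ndarray, beta: float, t_grid: np.ndarray) -> np.ndarray:
    """Stack of heat kernels exp(-beta*L*t) for every t (shape T x n x n).

    Column j of kernel[k] is the diffusion pattern at t_grid[k] from a unit
    impulse at node j, so a full seed sweep needs one eigendecomposition.
    """
    evals, evecs = np.linalg.eigh(np.asarray(L, dtype=float))
    out = np.empty((len(t_grid), L.shape[0], L.shape[0]))
    for k, t in enumerate(np.asarray(t_grid, dtype=float)):
        out[k] = (evecs * np.exp(-(beta * t) * evals)) @ evecs.T
    return out


def _pearson_columns(patterns: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``patterns`` against ``y`` (NaN -> 0-var guard)."""
    X = patterns - patterns.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((X**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X.T @ yc) / denom
    return np.where(denom > 0, r, np.nan)


def epicenter_sweep(
    sc: ConnectivityMatrix,
    atrophy: AtrophyMap,
    spec: DiffusionSpec | None = None,
) -> NDMResult:
    """Test every valid region as diffusion seed against the empirical map.

    For each seed i and time t, correlates exp(-beta*L*t) e_i with the
    atrophy t-statistics over valid nodes. The epicenter is the seed with the
    highest peak correlation; ties break to the lower parcel id.
    """
    spec = spec or DiffusionSpec()
    valid = sc.valid
    if valid.sum() < 3:
        raise DegenerateInputError("need at least 3 valid nodes for the sweep")
    y = np.asarray(atrophy.tstat, dtype=float)
    if y.shape[0] != sc.n_nodes:
        raise DimensionError("atrophy map length must match connectome size")
    y = y[valid]
    if np.ptp(y) == 0:
        raise ValueError("constant atrophy map: spatial correlation undefined")
    L = normalized_laplacian(sc, kind=spec.laplacian_kind)
    kernels = heat_kernels(L, spec.beta, spec.t_grid)
    n_valid = int(valid.sum())
    r_matrix = np.empty((n_valid, len(spec.t_grid)))
    for k in range(len(spec.t_grid)):
        r_matrix[:, k] = _pearson_columns(kernels[k], y)
    r_for_max = np.where(np.isnan(r_matrix), -np.inf, r_matrix)
    peak_idx = np.argmax(r_for_max, axis=1)
    peak_r = r_for_max[np.arange(n_valid), peak_idx]
    peak_t = spec.t_grid[peak_idx]
    seed_parcels = np.arange(1, sc.n_nodes + 1)[valid]
    order = np.lexsort((seed_parcels, -peak_r))
    ranking = seed_parcels[order]
    best = order[0]
    return NDMResult(
        seed_parcels=seed_parcels,
        t_grid=spec.t_grid.copy(),
        r_matrix=r_matrix,
        peak_r=peak_r,
        peak_t=peak_t,
        ranking=ranking,
        epicenter=int(seed_parcels[best]),
        t_opt=float(peak_t[best]),
        r_max=float(peak_r[best]),
    )
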
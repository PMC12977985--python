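"""Regional structure-function coupling.

For each region, the Spearman rank correlation between its structural
connectivity profile (row of the SC matrix) and its functional profile (row
of the FC matrix), excluding the self-connection. High coupling means
functional synchronization tracks direct anatomical pathways; low values
(decoupling) indicate communication via indirect routes or reorganization
detached from the structural scaffold. Zero SC entries are kept as data —
an absent pathway is informative, not missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datatypes import ConnectivityMatrix, DegenerateInputError, DimensionError, ParcelAtlas


@dataclass
class CouplingProfile:
    """Per-node SC-FC Spearman rho with validity; NaN where undefined."""

    rho: np.ndarray
    valid: np.ndarray  # node had a defined coupling value
    subject_id: str = ""

    def __post_init__(self) -> None:
        defined = self.rho[self.valid]
        if np.any(np.abs(defined) > 1 + 1e-12):
            raise ValueError("|rho| must not exceed 1")

    def mean_coupling(self) -> float:
        return float(np.mean(self.rho[self.valid]))


def sc_fc_coupling(sc: ConnectivityMatrix, fc: ConnectivityMatrix) -> CouplingProfile:
    """Spearman correlation of SC vs FC connectivity profiles per node.

    Both rows are restricted to the joint valid mask minus the node itself;
    ties get average ranks. A node with a constant SC (or FC) profile has no
    defined rank correlation and is flagged invalid rather than set to 0.
    """
    if sc.n_nodes != fc.n_nodes:
        raise DimensionError("SC and FC must share the atlas")
    joint = sc.valid & fc.valid
    if joint.sum() < 3:
        raise DegenerateInputError("need >= 3 jointly valid nodes for coupling")
    n = sc.n_nodes
    rho = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    jidx = np.flatnonzero(joint)
    for i in jidx:
        others = jidx[jidx != i]
        x = sc.weights[i, others]
        y = fc.weights[i, others]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # isolated / constant profile: rho undefined, stays flagged
        r = sps.spearmanr(x, y).statistic
        if np.isfinite(r):
            rho[i] = r
            defined[i] = True
    return CouplingProfile(rho=rho, valid=defined, subject_id=sc.subject_id or fc.subject_id)


def network_mean_coupling(profile: CouplingProfile, atlas: ParcelAtlas,
                          min_nodes: int = 2) -> dict[str, dict]:
    """Unweighted mean rho per canonical network.

    Networks with fewer than ``min_nodes`` defined values are flagged low-n
    and carry no mean.
    """
    if len(profile.rho) != atlas.n_parcels:
        raise DimensionError("coupling profile length must match atlas")
    out: dict[str, dict] = {}
    for network in dict.fromkeys(atlas.networks.tolist()):
        members = atlas.index_of(atlas.parcels_in_network(network))
        ok = members[profile.valid[members]]
        if len(ok) < min_nodes:
            out[network] = {"mean_rho": None, "n": int(len(ok)), "low_n": True}
        else:
            out[network] = {
                "mean_rho": float(profile.rho[ok].mean()),
                "n": int(len(ok)),
                "low_n": False,
            }
    return out
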
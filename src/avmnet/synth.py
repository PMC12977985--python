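"""Synthetic cohort generator.

No patient MRI is distributed with studies of this kind, so every downstream
stage is exercised on synthetic data carrying the statistical structure the
analysis assumes: a weighted, sparse, hub-bearing structural connectome;
functional connectivity statistically coupled to structure with controllable
coupling strength; spatially contiguous lesions over a toy voxel atlas;
morphometry whose group difference follows forward network diffusion from a
known seed; and cognitive scores whose variance is driven by white-matter
integrity rather than lesion volume (the headline dissociation).

Everything is deterministic under ``rng_seed``: independent child streams
are spawned per data component, so optional components (e.g. FC) can be
skipped without disturbing the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from . import io as avio
from .datatypes import (
    CANONICAL_NETWORKS,
    AtrophyMap,
    CognitiveBattery,
    ConnectivityMatrix,
    DegenerateInputError,
    ParcelAtlas,
    RegionalLesionProfile,
    SubjectRecord,
)
from .lesion import regional_lesion_proportion
from .ndm import diffuse, normalized_laplacian

logger = logging.getLogger("avmnet")

#: raw-score scale per neuropsychological test: (control mean, SD, latency?)
TEST_SPECS: dict[str, tuple[float, float, bool]] = {
    "MMSE": (27.0, 2.0, False),
    "MoCA": (26.0, 2.5, False),
    "Stroop_CW_time": (60.0, 15.0, True),
    "VerbalFluency": (18.0, 5.0, False),
    "DigitOrdering": (12.0, 3.0, False),
    "AVLT_DelayedRecall": (8.0, 2.5, False),
    "SDMT": (45.0, 10.0, False),
    "TrailMaking_time": (80.0, 25.0, True),
    "BostonNaming": (25.0, 3.0, False),
}

#: fixed domain membership (Verbal Fluency serves Executive and Language)
DOMAIN_MAP: dict[str, tuple[str, ...]] = {
    "Executive": ("Stroop_CW_time", "VerbalFluency", "DigitOrdering"),
    "Memory": ("AVLT_DelayedRecall",),
    "Attention/Speed": ("SDMT", "TrailMaking_time"),
    "Language": ("BostonNaming", "VerbalFluency"),
    "Global": ("MMSE", "MoCA"),
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic study.

    The defaults are the study conditions: 90 nodes (full-size 360
    supported), 44 patients vs 72 controls, SC density 0.2 with a 10%
    rich-club-like hub fraction, SC->FC coupling gamma 0.6, diffusion seed
    pattern taken at t* = 2.5, and a cognition model dominated by the
    white-matter integrity factor (cog_effect) with only a token lesion-load
    contribution (lesion_cog_effect), reproducing the integrity-not-volume
    dissociation.
    """

    n_nodes: int = 90
    n_patients: int = 44
    n_controls: int = 72
    sc_density: float = 0.2
    hub_fraction: float = 0.1
    coupling_strength: float = 0.6  # gamma in [0, 1]
    fc_noise_sd: float = 1.0
    fc_samples: int = 500
    lesion_center_parcel: int | None = None  # default: first DMN parcel
    lesion_extent: int = 48  # voxels; per-patient extents scatter around this
    ndm_seed_parcel: int | None = None  # default: lesion center
    ndm_time: float = 2.5
    atrophy_noise_sd: float = 0.1
    cog_effect: float = 2.5  # slope of cognition on WM integrity factor q
    lesion_cog_effect: float = 0.5  # slope on total lesion load (tiny variance)
    cog_noise_sd: float = 0.5
    morpho_effect: float = 0.15  # mm of thickness change per unit pattern
    sc_jitter_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sc_density", "hub_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 <= self.coupling_strength <= 1):
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need >= 2 subjects per group")
        if self.ndm_time <= 0:
            raise ValueError("ndm_time must be positive")


@dataclass
class SyntheticCohort:
    """Complete generated dataset plus ground truth."""

    config: SynthConfig
    atlas: ParcelAtlas
    subjects: list[SubjectRecord]
    sc: dict[str, ConnectivityMatrix]
    fc: dict[str, ConnectivityMatrix]
    lesions: dict[str, RegionalLesionProfile]
    lesion_masks: dict[str, np.ndarray]
    morphometry: pd.DataFrame  # subjects x parcels (thickness, mm)
    battery: CognitiveBattery
    truth: dict

    @property
    def patient_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects if s.group == "AVM"]

    @property
    def control_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects if s.group == "NC"]

    def covariate_frame(self) -> pd.DataFrame:
        return avio.cohort_to_frame(self.subjects).set_index("subject_id")


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def make_synthetic_atlas(n_nodes: int = 90, block_size: int = 4, voxel_size: float = 2.0) -> ParcelAtlas:
    """Toy atlas: parcels are cubic voxel blocks tiling a 3-D grid.

    Hemisphere splits at the half count; networks cycle through the seven
    canonical systems so each is spatially distributed. This synthetic
    assignment stands in for a real functional parcellation lookup.
    """
    a = int(np.ceil(n_nodes ** (1 / 3)))
    b = int(np.ceil(np.sqrt(n_nodes / a)))
    c = int(np.ceil(n_nodes / (a * b)))
    labels = np.zeros((a * block_size, b * block_size, c * block_size), dtype=int)
    pid = 0
    for ix in range(a):
        for iy in range(b):
            for iz in range(c):
                if pid >= n_nodes:
                    break
                pid += 1
                labels[
                    ix * block_size:(ix + 1) * block_size,
                    iy * block_size:(iy + 1) * block_size,
                    iz * block_size:(iz + 1) * block_size,
                ] = pid
    table = pd.DataFrame(
        {
            "parcel_id": np.arange(1, n_nodes + 1),
            "name": [f"P{i:03d}" for i in range(1, n_nodes + 1)],
            "hemisphere": ["L" if i <= n_nodes // 2 else "R" for i in range(1, n_nodes + 1)],
            "network": [CANONICAL_NETWORKS[(i - 1) % len(CANONICAL_NETWORKS)] for i in range(1, n_nodes + 1)],
            "node_volume": np.full(n_nodes, block_size**3),
        }
    )
    return ParcelAtlas(table=table, label_volume=labels, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# structural connectome
# ---------------------------------------------------------------------------

def gen_structural_connectome(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    return_coords: bool = False,
):
    """Distance-decaying weighted random geometric connectome with hubs.

    Nodes sit uniformly in the unit cube; edge probability and weight decay
    exponentially with Euclidean distance (lognormal weight multipliers), a
    ``hub_fraction`` of nodes gets boosted connection probability, and a
    minimum spanning tree over distances is added so the graph is always a
    single connected component.
    """
    n = config.n_nodes
    rng = rng or np.random.default_rng(config.rng_seed)
    coords = rng.uniform(size=(n, 3))
    d = squareform(pdist(coords))
    lam = 0.5
    prob = np.exp(-d / lam)
    hubs = rng.choice(n, size=max(1, round(config.hub_fraction * n)), replace=False)
    hub_mask = np.zeros(n, dtype=bool)
    hub_mask[hubs] = True
    boost = np.where(hub_mask[:, None] | hub_mask[None, :], 4.0, 1.0)
    # community structure: within-system pairs connect preferentially
    nets = np.arange(n) % len(CANONICAL_NETWORKS)
    boost = boost * np.where(nets[:, None] == nets[None, :], 3.0, 1.0)
    prob = prob * boost
    iu, ju = np.triu_indices(n, k=1)
    target_edges = config.sc_density * len(iu)
    prob_u = prob[iu, ju]
    prob_u = np.clip(prob_u * (target_edges / prob_u.sum()), 0.0, 1.0)
    has_edge = rng.random(len(iu)) < prob_u
    mult = rng.lognormal(mean=0.0, sigma=0.5, size=len(iu))
    w_u = np.where(has_edge, 10.0 * np.exp(-d[iu, ju] / lam) * mult, 0.0)
    W = np.zeros((n, n))
    W[iu, ju] = w_u
    W += W.T
    # guarantee a single component via the distance MST
    mst = minimum_spanning_tree(d).toarray()
    mi, mj = np.nonzero(mst)
    added = 0
    for i, j in zip(mi, mj):
        if W[i, j] == 0:
            w = 10.0 * np.exp(-d[i, j] / lam)
            W[i, j] = W[j, i] = w
            added += 1
    if added:
        logger.info("gen_structural_connectome: added %d spanning-tree edges", added)
    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    assert n_comp == 1
    sc = ConnectivityMatrix(weights=W, modality="SC", subject_id="template")
    if return_coords:
        return sc, coords
    return sc


# ---------------------------------------------------------------------------
# functional connectivity
# ---------------------------------------------------------------------------

def _scaled_adjacency(sc: ConnectivityMatrix, radius: float = 0.6) -> np.ndarray:
    A = sc.weights
    evals = np.linalg.eigvalsh(A)
    rho = np.max(np.abs(evals))
    if rho == 0:
        raise DegenerateInputError("zero structural matrix cannot be scaled")
    return A * (radius / rho)


def gen_functional_from_structural(
    sc: ConnectivityMatrix,
    gamma: float,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    n_samples: int = 500,
) -> ConnectivityMatrix:
    """FC as the sample correlation of a linear-Gaussian network process.

    x = gamma * A' x + eps with A' = SC rescaled to spectral radius 0.6 and
    eps ~ N(0, noise_sd^2) i.i.d., i.e. x = (I - gamma A')^{-1} eps. The
    implied covariance is (I - gamma A')^{-1} (I - gamma A')^{-T} (times
    noise variance), available analytically via
    :func:`analytic_fc_correlation`. Node-level SC-FC coupling rises
    monotonically with gamma.
    """
    if not (0 <= gamma <= 1):
        raise ValueError("gamma must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    n = sc.n_nodes
    At = _scaled_adjacency(sc)
    eps = rng.normal(0.0, noise_sd, size=(n_samples, n))
    X = np.linalg.solve(np.eye(n) - gamma * At, eps.T).T
    fc = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(fc, 0.0)
    return ConnectivityMatrix(weights=fc, modality="FC",
                              valid=sc.valid.copy(), subject_id=sc.subject_id)


def analytic_fc_correlation(sc: ConnectivityMatrix, gamma: float) -> np.ndarray:
    """Population correlation matrix of the linear-Gaussian FC model
    (independent of the noise SD); diagonal zeroed like generated FC."""
    n = sc.n_nodes
    M = np.linalg.inv(np.eye(n) - gamma * _scaled_adjacency(sc))
    cov = M @ M.T
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 0.0)
    return corr


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def gen_lesion_profile(
    atlas: ParcelAtlas,
    center_parcel: int,
    extent: int,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
) -> tuple[RegionalLesionProfile, np.ndarray]:
    """Grow a contiguous lesion of ``extent`` voxels from a center parcel.

    Voxels fill the center parcel first (nearest the parcel centroid first),
    then spill into surrounding brain voxels by distance, so an extent equal
    to half the parcel lesions exactly half of it. Growth is deterministic;
    the rng argument exists for API symmetry. Extents beyond the brain are
    capped (logged). Returns (per-parcel profile, boolean lesion grid).
    """
    del rng  # growth is deterministic
    if atlas.label_volume is None:
        raise ValueError("atlas has no label volume to grow a lesion in")
    labels = atlas.label_volume
    if center_parcel not in set(atlas.parcel_ids.tolist()):
        raise IndexError(f"unknown center parcel {center_parcel}")
    coords = np.argwhere(labels > 0)
    in_center = labels[tuple(coords.T)] == center_parcel
    if not np.any(in_center):
        raise ValueError(f"center parcel {center_parcel} has no voxels")
    centroid = coords[in_center].mean(axis=0)
    dist = np.linalg.norm(coords - centroid, axis=1)
    flat = np.ravel_multi_index(tuple(coords.T), labels.shape)
    # center-parcel voxels first, then the rest of the brain, each by distance
    order = np.lexsort((flat, dist, (~in_center).astype(int)))
    n_brain = len(coords)
    if extent > n_brain:
        logger.info("gen_lesion_profile: extent %d capped at brain size %d", extent, n_brain)
        extent = n_brain
    chosen = coords[order[:extent]]
    mask = np.zeros(labels.shape, dtype=bool)
    mask[tuple(chosen.T)] = True
    profile = regional_lesion_proportion(mask, labels, atlas, subject_id=subject_id)
    return profile, mask


# ---------------------------------------------------------------------------
# atrophy forward model
# ---------------------------------------------------------------------------

def gen_atrophy_from_seed(
    sc: ConnectivityMatrix,
    seed_parcel: int,
    t_star: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> AtrophyMap:
    """Forward-diffused deformation map from a known seed, plus noise.

    The unit impulse at ``seed_parcel`` is diffused to t*, standardized to
    zero mean / unit variance over valid nodes, and perturbed with
    N(0, noise_sd^2) noise — the ground-truth target for epicenter recovery.
    """
    if seed_parcel < 1 or seed_parcel > sc.n_nodes or not sc.valid[seed_parcel - 1]:
        raise IndexError(f"seed parcel {seed_parcel} is not a valid node")
    rng = rng or np.random.default_rng()
    L = normalized_laplacian(sc)
    vidx = np.flatnonzero(sc.valid)
    x0 = np.zeros(len(vidx))
    x0[np.flatnonzero(vidx == seed_parcel - 1)[0]] = 1.0
    x = diffuse(L, x0, beta=1.0, t=t_star)
    x = (x - x.mean()) / x.std()
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=len(x))
    tstat = np.full(sc.n_nodes, np.nan)
    tstat[vidx] = x
    return AtrophyMap(tstat=tstat, metric="thickness")


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def _jitter_matrix(W: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mult = rng.lognormal(mean=0.0, sigma=sd, size=len(iu))
    out = np.zeros_like(W)
    out[iu, ju] = W[iu, ju] * mult
    return out + out.T


def default_lesion_center(atlas: ParcelAtlas) -> int:
    """First DMN parcel — the synthetic lesion nests in the default mode network."""
    return int(atlas.parcels_in_network("DMN")[0])


def gen_cohort(config: SynthConfig, include_fc: bool = True) -> SyntheticCohort:
    """Generate the full synthetic study.

    Controls carry intact (jittered) copies of a shared structural template;
    patients additionally have every intra-DMN edge attenuated by a
    subject-specific white-matter integrity factor q ~ Uniform(0.3, 1) and a
    contiguous lesion grown from a DMN parcel with per-patient extent.
    Cognition follows cog_effect * q + lesion_cog_effect * lesion_load +
    demographic terms + noise with cog_effect dominating, so regression on
    integrity is significant while regression on lesion volume is not.
    Patient morphometry adds a forward-diffusion pattern from the configured
    seed, giving the group t-map the diffusion-model sweep should trace back.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    (sc_seed, subj_seed, lesion_seed, fc_seed, demo_seed,
     cog_seed, morpho_seed) = ss.spawn(7)
    atlas = make_synthetic_atlas(config.n_nodes)
    template = gen_structural_connectome(config, rng=np.random.default_rng(sc_seed))
    dmn = atlas.parcels_in_network("DMN")
    dmn_idx = atlas.index_of(dmn)
    # the associative core is never fully disconnected: guarantee a chain of
    # intra-DMN edges so the integrity factor always has substrate to act on
    fill_w = float(np.median(template.weights[template.weights > 0]))
    for a, b in zip(dmn_idx[:-1], dmn_idx[1:]):
        if template.weights[a, b] == 0:
            template.weights[a, b] = template.weights[b, a] = fill_w
            logger.info("gen_cohort: added intra-DMN chain edge %d-%d", a + 1, b + 1)
    center = config.lesion_center_parcel or default_lesion_center(atlas)
    ndm_seed = config.ndm_seed_parcel or center

    n_p, n_c = config.n_patients, config.n_controls
    ids = [f"AVM{i:03d}" for i in range(1, n_p + 1)] + [f"NC{i:03d}" for i in range(1, n_c + 1)]
    groups = ["AVM"] * n_p + ["NC"] * n_c

    # --- demographics (matched to the clinical cohort's printed summaries)
    demo_rng = np.random.default_rng(demo_seed)
    age = np.where(
        np.array(groups) == "AVM",
        np.clip(demo_rng.normal(40.34, 13.20, len(ids)), 18, 80),
        np.clip(demo_rng.normal(45.67, 14.93, len(ids)), 18, 80),
    )
    sex = np.where(
        demo_rng.random(len(ids)) < np.where(np.array(groups) == "AVM", 0.568, 0.403),
        "M", "F",
    )
    edu = np.where(
        np.array(groups) == "AVM",
        np.clip(demo_rng.normal(11.31, 4.41, len(ids)), 0, 22),
        np.clip(demo_rng.normal(13.03, 2.83, len(ids)), 0, 22),
    )
    mfd = np.abs(demo_rng.normal(0.15, 0.05, len(ids)))
    tiv = demo_rng.normal(1.5e6, 1.2e5, len(ids))
    seiz = demo_rng.random(len(ids)) < np.where(np.array(groups) == "AVM", 0.159, 0.0)
    subjects = [
        SubjectRecord(subject_id=s, group=g, age=float(a), sex=str(x),
                      education=float(e), mFD=float(m), TIV=float(t),
                      seizure=bool(z),
                      sm_grade=int(demo_rng.integers(1, 5)) if g == "AVM" else None)
        for s, g, a, x, e, m, t, z in zip(ids, groups, age, sex, edu, mfd, tiv, seiz)
    ]

    # --- structural connectomes and lesions
    subj_rng = np.random.default_rng(subj_seed)
    lesion_rng = np.random.default_rng(lesion_seed)
    q = np.ones(len(ids))
    q[:n_p] = subj_rng.uniform(0.3, 1.0, n_p)
    extents = np.rint(config.lesion_extent * lesion_rng.uniform(0.5, 2.0, n_p)).astype(int)
    sc_maps: dict[str, ConnectivityMatrix] = {}
    lesions: dict[str, RegionalLesionProfile] = {}
    lesion_masks: dict[str, np.ndarray] = {}
    for k, sid in enumerate(ids):
        W = _jitter_matrix(template.weights, config.sc_jitter_sd, subj_rng)
        if groups[k] == "AVM":
            sub = np.ix_(dmn_idx, dmn_idx)
            W[sub] = W[sub] * q[k]
            profile, mask = gen_lesion_profile(atlas, center, int(extents[k]), subject_id=sid)
            lesions[sid] = profile
            lesion_masks[sid] = mask
        else:
            lesions[sid] = RegionalLesionProfile(
                proportion=np.zeros(config.n_nodes), total_lesion_load=0.0, subject_id=sid
            )
        sc_maps[sid] = ConnectivityMatrix(weights=W, modality="SC", subject_id=sid)

    # --- functional connectomes (independent stream; skippable)
    fc_maps: dict[str, ConnectivityMatrix] = {}
    if include_fc:
        fc_rng = np.random.default_rng(fc_seed)
        for sid in ids:
            fc_maps[sid] = gen_functional_from_structural(
                sc_maps[sid], config.coupling_strength, config.fc_noise_sd,
                rng=fc_rng, n_samples=config.fc_samples,
            )

    # --- morphometry with forward-diffusion group effect
    morpho_rng = np.random.default_rng(morpho_seed)
    pattern = gen_atrophy_from_seed(template, ndm_seed, config.ndm_time).tstat
    parcel_base = 2.5 + morpho_rng.normal(0.0, 0.1, config.n_nodes)
    rows = []
    for k, sid in enumerate(ids):
        v = parcel_base + morpho_rng.normal(0.0, 0.1, config.n_nodes)
        if groups[k] == "AVM":
            v = v + config.morpho_effect * pattern
        rows.append(v)
    morphometry = pd.DataFrame(
        rows, index=ids, columns=[f"P{i:03d}" for i in range(1, config.n_nodes + 1)]
    )

    # --- cognition
    cog_rng = np.random.default_rng(cog_seed)
    loads = np.array([lesions[sid].total_lesion_load for sid in ids])
    latent = (
        config.cog_effect * q
        + config.lesion_cog_effect * loads
        - 0.02 * (age - 45.0)
        + 0.05 * (edu - 12.0)
        + cog_rng.normal(0.0, config.cog_noise_sd, len(ids))
    )
    delta = latent - config.cog_effect  # centered at the healthy expectation
    scores = {}
    for test, (mu, sd, latency) in TEST_SPECS.items():
        noise = cog_rng.normal(0.0, 1.0, len(ids))
        signal = 0.7 * delta + 0.5 * noise
        scores[test] = mu + sd * (-signal if latency else signal)
    battery = CognitiveBattery(
        scores=pd.DataFrame(scores, index=ids),
        latency_flags={t: lat for t, (_, _, lat) in TEST_SPECS.items()},
        domain_map=DOMAIN_MAP,
    )

    truth = {
        "q": dict(zip(ids, q)),
        "lesion_extents": dict(zip(ids[:n_p], extents.tolist())),
        "lesion_center": center,
        "ndm_seed_parcel": ndm_seed,
        "ndm_time": config.ndm_time,
        "pattern": pattern,
        "template": template,
        "latent_cognition": dict(zip(ids, latent)),
    }
    return SyntheticCohort(
        config=config, atlas=atlas, subjects=subjects, sc=sc_maps, fc=fc_maps,
        lesions=lesions, lesion_masks=lesion_masks, morphometry=morphometry,
        battery=battery, truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write the cohort in the interchange formats the readers consume."""
    out = Path(out_dir)
    (out / "sc").mkdir(parents=True, exist_ok=True)
    (out / "fc").mkdir(exist_ok=True)
    (out / "lesions").mkdir(exist_ok=True)
    avio.write_atlas(cohort.atlas, out / "atlas.csv")
    if cohort.atlas.label_volume is not None:
        avio.write_volume(cohort.atlas.label_volume, out / "labels.nii.gz",
                          cohort.atlas.voxel_size)
    avio.cohort_to_frame(cohort.subjects).to_csv(out / "cohort.csv", index=False)
    cohort.battery.scores.rename_axis("subject_id").to_csv(out / "cognition.csv")
    cohort.morphometry.rename_axis("subject_id").to_csv(out / "morphometry.csv")
    for sid, mat in cohort.sc.items():
        avio.write_matrix(mat, out / "sc" / f"{sid}.tsv", cohort.atlas)
    for sid, mat in cohort.fc.items():
        avio.write_matrix(mat, out / "fc" / f"{sid}.tsv", cohort.atlas)
    for sid, mask in cohort.lesion_masks.items():
        avio.write_volume(mask, out / "lesions" / f"{sid}.nii.gz", cohort.atlas.voxel_size)
    return out


def replicate_config(config: SynthConfig, seed: int) -> SynthConfig:
    """Same study conditions under a different seed (for power simulations)."""
    return replace(config, rng_seed=seed)
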
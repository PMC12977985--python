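"""Lesion burden metrics and cognitive score standardization.

Lesion burden is quantified at two levels: Total Lesion Load (lesioned
voxels over intracranial voxels) and the Regional Lesion Proportion (the
lesioned fraction of each atlas parcel). The Default Mode Network is
summarized by two competing predictors: mean intra-DMN structural edge
weight (white-matter integrity) and mean DMN parcel lesion proportion
(local gray-matter damage).

Cognitive raw scores are z-scored against the healthy-control distribution,
latency metrics are inverted so higher always means better, tests are
averaged into composite domains, and demographic variance (age, sex,
education) is removed by OLS residualization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    CognitiveBattery,
    ConnectivityMatrix,
    DegenerateInputError,
    ParcelAtlas,
    RegionalLesionProfile,
)


def total_lesion_load(lesion_grid: np.ndarray, tiv_voxels: int) -> float:
    """Aggregate lesioned voxels divided by total intracranial voxels."""
    if tiv_voxels <= 0:
        raise ValueError("TIV voxel count must be positive")
    return float(np.count_nonzero(lesion_grid)) / float(tiv_voxels)


def regional_lesion_proportion(
    lesion_grid: np.ndarray,
    label_volume: np.ndarray,
    atlas: ParcelAtlas,
    subject_id: str = "",
) -> RegionalLesionProfile:
    """Lesioned fraction of every atlas parcel.

    proportion_p = |lesion AND parcel_p| / |parcel_p|. Parcels absent from
    the label volume get NaN (flagged missing), never a silent 0. Total
    lesion load uses all nonzero-label voxels as the intracranial volume.
    """
    if lesion_grid.shape != label_volume.shape:
        raise ValueError("lesion mask and label volume shapes differ")
    n = atlas.n_parcels
    mask = np.asarray(lesion_grid, dtype=bool)
    labels = np.asarray(label_volume)
    parcel_sizes = np.bincount(labels.ravel(), minlength=n + 1)[1 : n + 1]
    lesioned = np.bincount(labels.ravel(), weights=mask.ravel().astype(float), minlength=n + 1)[1 : n + 1]
    prop = np.full(n, np.nan)
    nz = parcel_sizes > 0
    prop[nz] = lesioned[nz] / parcel_sizes[nz]
    tiv = int(np.count_nonzero(labels))
    load = float(mask[labels > 0].sum()) / tiv if tiv > 0 else 0.0
    return RegionalLesionProfile(proportion=prop, total_lesion_load=load, subject_id=subject_id)


def dmn_integrity(sc: ConnectivityMatrix, dmn_parcels: np.ndarray) -> float:
    """Mean structural edge weight over unordered pairs of valid DMN parcels.

    Zero-weight pairs count as edges of weight 0 (absent pathways are data).
    This is the white-matter integrity proxy: attenuation of any intra-DMN
    edge can only lower it.
    """
    idx = np.asarray(dmn_parcels, dtype=int) - 1
    idx = idx[sc.valid[idx]]
    if len(idx) < 2:
        raise DegenerateInputError("need >= 2 valid DMN parcels for integrity")
    sub = sc.weights[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    return float(sub[iu, ju].mean())


def dmn_local_lesion_load(profile: RegionalLesionProfile, dmn_parcels: np.ndarray) -> float:
    """Mean lesion proportion over DMN parcels (size-invariant)."""
    idx = np.asarray(dmn_parcels, dtype=int) - 1
    if len(idx) == 0:
        raise ValueError("empty DMN parcel set")
    vals = profile.proportion[idx]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no DMN parcel has a defined lesion proportion")
    return float(vals.mean())


def zscore_battery(
    battery: CognitiveBattery,
    control_ids: list[str] | pd.Index,
) -> pd.DataFrame:
    """Standardize raw test scores against the healthy-control group and
    average into composite domains.

    z = (raw - mean_NC) / sd_NC per test; latency-flagged tests are negated
    so higher z is always better performance. Domain score = mean of member
    test z-scores; the Global domain is the mean of the MMSE and MoCA
    z-scores. Returns subjects x domains DataFrame.
    """
    scores = battery.scores
    ctrl = scores.loc[scores.index.intersection(control_ids)]
    z = pd.DataFrame(index=scores.index)
    for test in scores.columns:
        mu = ctrl[test].mean()
        sd = ctrl[test].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"control SD is zero/undefined for test {test!r}")
        col = (scores[test] - mu) / sd
        if battery.latency_flags.get(test, False):
            col = -col
        z[test] = col
    domains = pd.DataFrame(index=scores.index)
    for domain, tests in battery.domain_map.items():
        domains[domain] = z[list(tests)].mean(axis=1)
    return domains


def residualize(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Regress covariates out of each score column; return standardized residuals.

    Covariates are entered in a design with intercept (categorical 'sex'
    coded 0/1). Residuals are divided by their sample SD, so the output is
    orthogonal to every design column and has unit variance. Raises on
    rank-deficient designs (naming the collinear columns) and on residuals
    with zero variance.
    """
    cov = covariates.copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "M").astype(float)
    X = np.column_stack([np.ones(len(cov))] + [cov[c].to_numpy(dtype=float) for c in cov.columns])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design (rank {rank} < {X.shape[1]}); "
            f"columns: {['intercept', *cov.columns]}"
        )
    if len(cov) <= X.shape[1]:
        raise ValueError("need n > number of covariates + 1")
    out = pd.DataFrame(index=scores.index)
    Q, _ = np.linalg.qr(X)
    for col in scores.columns:
        y = scores[col].to_numpy(dtype=float)
        resid = y - Q @ (Q.T @ y)
        sd = resid.std(ddof=1)
        if sd < 1e-12:
            raise ValueError(
                f"residuals of {col!r} have zero variance (scores are an exact "
                "linear function of the covariates); cannot standardize"
            )
        out[col] = resid / sd
    return out
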
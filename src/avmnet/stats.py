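"""Inferential machinery: group tests, OLS / robust regression, FDR,
edgewise FC comparison, morphometry t-maps, and the sensitivity sweep.

Two-sample comparisons of continuous summaries use the Welch
(unequal-variance) t by default; 2x2 categorical tables use the Yates
continuity-corrected chi-square. Brain-behavior models are fit by OLS and,
for outlier robustness, by Huber M-estimation (IRLS with tuning constant
c = 1.345 on the MAD scale). Multiple testing is controlled with the
Benjamini-Hochberg step-up FDR within each analysis family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .datatypes import AtrophyMap, ConnectivityMatrix

logger = logging.getLogger("avmnet")


@dataclass
class RegressionResult:
    """Per-term estimates from one fitted linear model."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray  # t (OLS) or z (RLM)
    p: np.ndarray
    method: str  # "OLS" or "HuberRLM"
    n: int
    adj_r2: float | None = None
    converged: bool = True

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "beta": self.beta, "se": self.se,
             "stat": self.stat, "p": self.p}
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {"beta": float(self.beta[i]), "se": float(self.se[i]),
                "stat": float(self.stat[i]), "p": float(self.p[i])}


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def welch_t(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int) -> dict:
    """Welch two-sample t from group summaries, with Satterthwaite df."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 and sd2 <= 0:
        raise ValueError("at least one group SD must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> dict:
    """Pearson chi-square on a 2x2 table (Yates-corrected by default)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    res = sps.chi2_contingency(table, correction=yates)
    return {"chi2": float(res.statistic), "p": float(res.pvalue), "df": 1}


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> dict:
    """Mann-Whitney U with tie-corrected, continuity-corrected normal Z.

    p is by exact enumeration when n1*n2 <= 400 and the data are tie-free,
    otherwise from the continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    if len(tie_counts) == 1:
        warnings.warn("all values tied across both samples", stacklevel=2)
        return {"U": n1 * n2 / 2.0, "Z": 0.0, "p": 1.0}
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma if sigma > 0 else 0.0
    has_ties = np.any(tie_counts > 1)
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return {"U": float(u1), "Z": float(z), "p": p}


def shapiro_wilk(sample: Sequence[float]) -> dict:
    """Shapiro-Wilk normality test (scipy-backed)."""
    sample = np.asarray(sample, dtype=float)
    if not (3 <= len(sample) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(sample) == 0:
        raise ValueError("constant sample: W undefined")
    res = sps.shapiro(sample)
    return {"W": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def _design(X: np.ndarray | pd.DataFrame, terms: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns) if terms is None else list(terms)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if terms is None:
            terms = [f"x{i}" for i in range(X.shape[1])]
    return X, list(terms)


def ols_fit(
    y: Sequence[float],
    X: np.ndarray | pd.DataFrame,
    terms: Sequence[str] | None = None,
    standardized: bool = False,
) -> RegressionResult:
    """OLS with intercept; optionally on z-scored y and predictors so the
    coefficients are standardized betas."""
    y = np.asarray(y, dtype=float)
    X, terms = _design(X, terms)
    if standardized:
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0) or y.std(ddof=1) == 0:
            bad = [terms[i] for i in np.flatnonzero(sds == 0)] or ["<response>"]
            raise ValueError(f"cannot standardize constant column(s): {bad}")
        y = (y - y.mean()) / y.std(ddof=1)
        X = (X - X.mean(axis=0)) / sds
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        terms=["const", *terms],
        beta=np.asarray(fit.params),
        se=np.asarray(fit.bse),
        stat=np.asarray(fit.tvalues),
        p=np.asarray(fit.pvalues),
        method="OLS",
        n=len(y),
        adj_r2=float(fit.rsquared_adj),
    )


def huber_rlm_fit(
    y: Sequence[float],
    X: np.ndarray | pd.DataFrame,
    terms: Sequence[str] | None = None,
    c: float = 1.345,
    maxiter: int = 50,
    tol: float = 1e-8,
) -> RegressionResult:
    """Huber M-estimation by IRLS (tuning c on the MAD scale).

    Non-convergence within ``maxiter`` iterations is flagged on the result,
    never raised.
    """
    y = np.asarray(y, dtype=float)
    X, terms = _design(X, terms)
    design = sm.add_constant(X, has_constant="add")
    model = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=c))
    fit = model.fit(maxiter=maxiter, tol=tol, scale_est="mad", conv="coefs")
    n_iter = len(fit.fit_history.get("params", [])) or maxiter
    return RegressionResult(
        terms=["const", *terms],
        beta=np.asarray(fit.params),
        se=np.asarray(fit.bse),
        stat=np.asarray(fit.tvalues),
        p=np.asarray(fit.pvalues),
        method="HuberRLM",
        n=len(y),
        converged=bool(n_iter < maxiter),
    )


def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return {"adjusted": adj, "reject": reject}


# ---------------------------------------------------------------------------
# vectorized mass-univariate OLS (edges / parcels)
# ---------------------------------------------------------------------------

def _mass_ols_tstats(Y: np.ndarray, X: np.ndarray, term_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """t and p of one design column across many response columns at once."""
    n, p_terms = X.shape
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    dof = n - p_terms
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv_diag = np.linalg.inv(X.T @ X)[term_idx, term_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = B[term_idx] / np.sqrt(sigma2 * xtx_inv_diag)
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return t, p


def edgewise_group_ttest(
    fc_patients: Sequence[ConnectivityMatrix],
    fc_controls: Sequence[ConnectivityMatrix],
    covariates: pd.DataFrame | None = None,
    k: int = 200,
    missing_frac: float = 0.5,
) -> dict:
    """Edgewise group comparison of Fisher-z transformed FC.

    Per upper-triangle edge, the t-statistic of the group term (patient = 1)
    from OLS of z(FC) on group + covariates (covariate rows ordered patients
    then controls; mFD belongs here for functional analyses). Edges missing
    (node invalid) in more than ``missing_frac`` of subjects are excluded.
    Returns the symmetric T and p matrices plus the top-k hyper- (most
    positive t) and hypo-connected (most negative t) edge sets as (i, j)
    parcel-id pairs.
    """
    mats = list(fc_patients) + list(fc_controls)
    if len(fc_patients) < 3 or len(fc_controls) < 3:
        raise ValueError("need >= 3 subjects per group")
    n = mats[0].n_nodes
    iu, ju = np.triu_indices(n, k=1)
    S, E = len(mats), len(iu)
    Y = np.empty((S, E))
    present = np.empty((S, E), dtype=bool)
    for s, m in enumerate(mats):
        w = np.clip(m.weights, -1 + 1e-7, 1 - 1e-7)
        Y[s] = np.arctanh(w[iu, ju])
        ok = m.valid[iu] & m.valid[ju]
        present[s] = ok
    group = np.concatenate([np.ones(len(fc_patients)), np.zeros(len(fc_controls))])
    cols = [np.ones(S), group]
    if covariates is not None:
        cov = covariates.copy()
        if "sex" in cov.columns and cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"] == "M").astype(float)
        cols += [cov[c].to_numpy(dtype=float) for c in cov.columns]
    X = np.column_stack(cols)
    frac_present = present.mean(axis=0)
    usable = frac_present > (1.0 - missing_frac)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("edgewise_group_ttest: excluded %d edges with >%d%% missing",
                    n_dropped, int(missing_frac * 100))
    t = np.full(E, np.nan)
    p = np.full(E, np.nan)
    complete = usable & np.all(present, axis=0)
    if np.any(complete):
        t[complete], p[complete] = _mass_ols_tstats(Y[:, complete], X, term_idx=1)
    for e in np.flatnonzero(usable & ~complete):
        rows = present[:, e]
        Xr = X[rows]
        # a group effect needs both groups and a full-rank restricted design
        if rows.sum() <= X.shape[1] or np.ptp(Xr[:, 1]) == 0 or \
                np.linalg.matrix_rank(Xr) < Xr.shape[1]:
            continue
        te, pe = _mass_ols_tstats(Y[rows, e][:, None], Xr, term_idx=1)
        t[e], p[e] = te[0], pe[0]
    tmat = np.full((n, n), np.nan)
    pmat = np.full((n, n), np.nan)
    tmat[iu, ju] = tmat[ju, iu] = t
    pmat[iu, ju] = pmat[ju, iu] = p
    defined = np.flatnonzero(np.isfinite(t))
    if k > len(defined):
        warnings.warn(f"k={k} exceeds {len(defined)} defined edges; returning all",
                      stacklevel=2)
        k = len(defined)
    order = defined[np.argsort(t[defined])]
    hyper_idx = order[::-1][:k]
    hypo_idx = order[:k]
    hyper = [(int(iu[e] + 1), int(ju[e] + 1)) for e in hyper_idx if t[e] > 0]
    hypo = [(int(iu[e] + 1), int(ju[e] + 1)) for e in hypo_idx if t[e] < 0]
    return {"tmat": tmat, "pmat": pmat, "hyper_edges": hyper, "hypo_edges": hypo}


def aggregate_edge_strength(fc_subject: ConnectivityMatrix, edge_set: Sequence[tuple[int, int]]) -> float:
    """Mean FC weight over a fixed edge set for one subject."""
    if len(edge_set) == 0:
        raise ValueError("edge set is empty")
    vals = [fc_subject.weights[i - 1, j - 1] for i, j in edge_set]
    return float(np.mean(vals))


def regional_morphometry_tmap(
    values: pd.DataFrame,
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
    patient_label: str = "AVM",
    metric: str = "thickness",
) -> AtrophyMap:
    """Per-parcel group-difference t-statistics adjusted for covariates.

    ``values``: subjects x parcels morphometry table; ``covariates``
    typically age, sex, TIV (the structural family). Positive t = patient >
    control. Constant parcels get NaN (flagged, not zero). The result is the
    empirical deformation map the diffusion-model sweep consumes.
    """
    Y = values.to_numpy(dtype=float)
    groups = np.asarray(groups)
    g = (groups == patient_label).astype(float)
    if g.sum() < 3 or (1 - g).sum() < 3:
        raise ValueError("need >= 3 subjects per group")
    cols = [np.ones(len(g)), g]
    if covariates is not None:
        cov = covariates.copy()
        if "sex" in cov.columns and cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"] == "M").astype(float)
        cols += [cov[c].to_numpy(dtype=float) for c in cov.columns]
    X = np.column_stack(cols)
    t, _ = _mass_ols_tstats(Y, X, term_idx=1)
    constant = np.ptp(Y, axis=0) == 0
    t[constant] = np.nan
    return AtrophyMap(tstat=t, metric=metric, sign_convention="patient_minus_control")


# ---------------------------------------------------------------------------
# sensitivity sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Stability of a regression term across the threshold grid."""

    table: pd.DataFrame = field(repr=False)
    robust: bool = False
    degenerate_grid: bool = False


def sensitivity_sweep(
    fit_at: Callable[[float, float], dict],
    density_grid: Sequence[float] = (0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20),
    lesion_cutoff_grid: Sequence[float] = (0.5,),
    alpha: float = 0.05,
) -> SweepResult:
    """Re-fit the key regression across sparsity and lesion-cutoff grids.

    ``fit_at(density, cutoff)`` must return {'beta': float, 'p': float} for
    the term of interest. The effect is robust when every grid cell succeeds,
    the coefficient sign is constant, and significance at ``alpha`` holds
    everywhere. A single-cell grid is trivially robust and flagged
    degenerate.
    """
    rows = []
    for dens in density_grid:
        for cut in lesion_cutoff_grid:
            try:
                res = fit_at(float(dens), float(cut))
                rows.append({"density": dens, "lesion_cutoff": cut,
                             "beta": res["beta"], "p": res["p"],
                             "significant": res["p"] < alpha, "failed": False})
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                logger.warning("sweep cell (density=%s, cutoff=%s) failed: %s", dens, cut, exc)
                rows.append({"density": dens, "lesion_cutoff": cut,
                             "beta": np.nan, "p": np.nan,
                             "significant": False, "failed": True})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    degenerate = len(table) == 1
    if len(ok) == len(table) and len(ok) > 0:
        signs = np.sign(ok["beta"].to_numpy())
        robust = bool(np.all(signs == signs[0]) and ok["significant"].all())
    else:
        robust = False
    return SweepResult(table=table, robust=robust, degenerate_grid=degenerate)
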
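"""End-to-end analysis pipeline.

Stage order mirrors the study: generate (or load) the cohort, build
analysis-ready networks, compute graph topology, structure-function
coupling, the diffusion-model epicenter sweep with virtual-lesion
resilience, and finally the inferential models with the sensitivity sweep.
Each stage writes its outputs before the next starts; a failure halts the
run with the stage named and leaves a ``.partial`` marker. Reruns with the
same config and seed are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as avio
from .coupling import network_mean_coupling, sc_fc_coupling
from .datatypes import ConnectivityMatrix
from .lesion import (
    dmn_integrity,
    dmn_local_lesion_load,
    residualize,
    zscore_battery,
)
from .metrics import (
    clustering_coefficient,
    global_efficiency,
    node_strength_rank,
    virtual_lesion,
)
from .ndm import DiffusionSpec, epicenter_sweep
from .network import apply_lesion_mask, proportional_threshold
from .stats import (
    bh_fdr,
    chi2_2x2,
    edgewise_group_ttest,
    huber_rlm_fit,
    mann_whitney,
    ols_fit,
    regional_morphometry_tmap,
    sensitivity_sweep,
    welch_t,
)
from .synth import SynthConfig, gen_cohort, write_dataset

logger = logging.getLogger("avmnet")

STAGES = ("synth", "build", "metrics", "coupling", "ndm", "stats")


@dataclass
class PipelineConfig:
    """Single configuration for the whole run (YAML-serializable).

    Covariate lists follow the stratified strategy: structural models adjust
    for age/sex/TIV, functional models additionally for mFD, cognitive
    models for age/sex/education.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    density: float = 0.15
    density_grid: tuple = (0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20)
    lesion_cutoff: float = 0.5
    lesion_cutoff_grid: tuple = (0.5,)
    beta: float = 1.0
    t_max: float = 10.0
    t_step: float = 0.05
    n_null: int = 1000
    rng_seed: int = 7
    hyper_edge_k: int = 200
    structural_covariates: tuple = ("age", "sex", "TIV")
    functional_covariates: tuple = ("age", "sex", "TIV", "mFD")
    cognitive_covariates: tuple = ("age", "sex", "education")
    write_data: bool = True

    def diffusion_spec(self) -> DiffusionSpec:
        return DiffusionSpec(beta=self.beta,
                             t_grid=np.arange(0.0, self.t_max + 1e-9, self.t_step))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig(**d["synth"])
        for key in ("density_grid", "lesion_cutoff_grid", "structural_covariates",
                    "functional_covariates", "cognitive_covariates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Aggregate every config problem into one list (never first-fail)."""
    errors: list[str] = []
    if not (0 < config.density <= 1):
        errors.append("density must lie in (0, 1]")
    for d in config.density_grid:
        if not (0 < d <= 1):
            errors.append(f"density grid value {d} outside (0, 1]")
    if not (0 <= config.lesion_cutoff <= 1):
        errors.append("lesion_cutoff must lie in [0, 1]")
    if config.beta <= 0:
        errors.append("beta must be positive")
    if config.t_step <= 0 or config.t_max <= 0:
        errors.append("t grid must have positive extent and step")
    if config.n_null < 1:
        errors.append("n_null must be >= 1")
    try:
        SynthConfig(**dataclasses.asdict(config.synth))
    except (ValueError, TypeError) as exc:
        errors.append(f"synth config invalid: {exc}")
    return errors


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _covariates(frame: pd.DataFrame, names: tuple, ids: list[str]) -> pd.DataFrame:
    return frame.loc[ids, list(names)].copy()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the report mapping (also on disk as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid pipeline config: " + "; ".join(errors))
    report: dict = {
        "manifest": {
            "config_hash": config_hash(config),
            "seed": config.rng_seed,
            "avmnet_version": __version__,
        }
    }
    marker = out / ".partial"
    marker.touch()
    state: dict = {}
    t0 = time.time()
    for stage in STAGES:
        t_stage = time.time()
        try:
            _STAGE_FNS[stage](config, state, report, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", stage, time.time() - t_stage)
    avio.write_report(report, out / "report.json")
    runtime = round(time.time() - t0, 2)
    (out / "runtime.txt").write_text(f"{runtime}\n")  # kept out of the hashed report
    report["manifest"]["runtime_s"] = runtime
    marker.unlink(missing_ok=True)
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synth(config: PipelineConfig, state: dict, report: dict, out: Path) -> None:
    cohort = gen_cohort(config.synth)
    if config.write_data:
        write_dataset(cohort, out / "data")
    state["cohort"] = cohort
    report["synth"] = {
        "n_patients": len(cohort.patient_ids),
        "n_controls": len(cohort.control_ids),
        "n_nodes": config.synth.n_nodes,
        "lesion_center": cohort.truth["lesion_center"],
        "ndm_seed_parcel": cohort.truth["ndm_seed_parcel"],
    }


def _stage_build(config: PipelineConfig, state: dict, report: dict, out: Path) -> None:
    cohort = state["cohort"]
    masked_sc, masked_fc, thr_sc, thr_fc = {}, {}, {}, {}
    excluded = {}
    for sid in [s.subject_id for s in cohort.subjects]:
        sc = apply_lesion_mask(cohort.sc[sid], cohort.lesions[sid], config.lesion_cutoff)
        masked_sc[sid] = sc
        thr_sc[sid] = proportional_threshold(sc, config.density)
        excluded[sid] = int((~sc.valid).sum())
        if sid in cohort.fc:
            fc = apply_lesion_mask(cohort.fc[sid], cohort.lesions[sid], config.lesion_cutoff)
            masked_fc[sid] = fc
            thr_fc[sid] = proportional_threshold(fc, config.density)
    state.update(masked_sc=masked_sc, masked_fc=masked_fc, thr_sc=thr_sc, thr_fc=thr_fc)
    report["build"] = {
        "density": config.density,
        "lesion_cutoff": config.lesion_cutoff,
        "excluded_nodes": excluded,
    }
    avio.write_table(
        pd.DataFrame({"subject_id": list(excluded), "n_excluded": list(excluded.values())}),
        out / "excluded_nodes.tsv",
    )


def _stage_metrics(config: PipelineConfig, state: dict, report: dict, out: Path) -> None:
    cohort = state["cohort"]
    rows = []
    for s in cohort.subjects:
        sid = s.subject_id
        row = {"subject_id": sid, "group": s.group,
               "E_glob_sc": global_efficiency(state["thr_sc"][sid]),
               "C_sc": clustering_coefficient(state["thr_sc"][sid])}
        if sid in state["thr_fc"]:
            row["E_glob_fc"] = global_efficiency(state["thr_fc"][sid])
            row["C_fc"] = clustering_coefficient(state["thr_fc"][sid])
        rows.append(row)
    df = pd.DataFrame(rows)
    avio.write_table(df, out / "graph_metrics.tsv")
    state["graph_metrics"] = df
    grp = df.groupby("group")["E_glob_sc"].agg(["mean", "std", "count"])
    t_eff = welch_t(grp.loc["AVM", "mean"], grp.loc["AVM", "std"], int(grp.loc["AVM", "count"]),
                    grp.loc["NC", "mean"], grp.loc["NC", "std"], int(grp.loc["NC", "count"]))
    report["metrics"] = {
        "mean_E_glob_sc": {g: float(m) for g, m in df.groupby("group")["E_glob_sc"].mean().items()},
        "sc_efficiency_group_test": t_eff,
    }


def _stage_coupling(config: PipelineConfig, state: dict, report: dict, out: Path) -> None:
    cohort = state["cohort"]
    if not state["masked_fc"]:
        report["coupling"] = {"skipped": "no functional data"}
        return
    rows, mean_rho = [], {}
    for s in cohort.subjects:
        sid = s.subject_id
        prof = sc_fc_coupling(state["masked_sc"][sid], state["masked_fc"][sid])
        mean_rho[sid] = prof.mean_coupling()
        nets = network_mean_coupling(prof, cohort.atlas)
        for net, v in nets.items():
            rows.append({"subject_id": sid, "group": s.group, "network": net,
                         "mean_rho": v["mean_rho"], "n": v["n"], "low_n": v["low_n"]})
    df = pd.DataFrame(rows)
    avio.write_table(df, out / "coupling_by_network.tsv")
    state["coupling_mean"] = mean_rho
    by_group = {}
    for g in ("AVM", "NC"):
        sids = [s.subject_id for s in cohort.subjects if s.group == g]
        by_group[g] = float(np.mean([mean_rho[s] for s in sids]))
    report["coupling"] = {"mean_rho_by_group": by_group}


def _stage_ndm(config: PipelineConfig, state: dict, report: dict, out: Path) -> None:
    cohort = state["cohort"]
    cov_frame = cohort.covariate_frame()
    ids = [s.subject_id for s in cohort.subjects]
    groups = [s.group for s in cohort.subjects]
    atrophy = regional_morphometry_tmap(
        cohort.morphometry.loc[ids], groups,
        covariates=_covariates(cov_frame, config.structural_covariates, ids),
    )
    # group-representative structural network: mean over intact control SC
    ctrl = [state["masked_sc"][sid].weights for sid in cohort.control_ids]
    mean_sc = ConnectivityMatrix(weights=np.mean(ctrl, axis=0), modality="SC",
                                 subject_id="mean_NC")
    result = epicenter_sweep(mean_sc, atrophy, config.diffusion_spec())
    ranks, tied = node_strength_rank(mean_sc)
    vl_rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 9]))
    vl = virtual_lesion(mean_sc, result.epicenter, n_null=config.n_null, rng=vl_rng)
    ranking = pd.DataFrame({
        "parcel_id": result.seed_parcels,
        "peak_r": result.peak_r,
        "t_opt": result.peak_t,
    }).sort_values("peak_r", ascending=False, kind="mergesort")
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    avio.write_table(ranking, out / "epicenter_ranking.tsv")
    rmat = pd.DataFrame(result.r_matrix, index=result.seed_parcels,
                        columns=[f"{t:.2f}" for t in result.t_grid])
    rmat.rename_axis("parcel_id").reset_index().pipe(avio.write_table, out / "ndm_r_matrix.tsv")
    true_seed = cohort.truth["ndm_seed_parcel"]
    seed_rank = int(np.flatnonzero(result.ranking == true_seed)[0] + 1)
    report["ndm"] = {
        "epicenter": result.epicenter,
        "t_opt": result.t_opt,
        "r_max": result.r_max,
        "true_seed_parcel": true_seed,
        "true_seed_rank": seed_rank,
        "epicenter_strength_rank": int(ranks[result.epicenter - 1]),
        "strength_rank_tied": tied,
        "virtual_lesion": {
            "delta_pct": vl.delta_pct,
            "p": vl.p_value,
            "E_base": vl.E_base,
            "E_removed": vl.E_removed,
            "n_null": vl.n_null,
        },
    }
    state["atrophy"] = atrophy
    state["mean_sc"] = mean_sc


def _stage_stats(config: PipelineConfig, state: dict, report: dict, out: Path) -> None:
    cohort = state["cohort"]
    cov_frame = cohort.covariate_frame()
    ids = [s.subject_id for s in cohort.subjects]
    pids, cids = cohort.patient_ids, cohort.control_ids

    # Table-1-style demographics
    age_p = cov_frame.loc[pids, "age"]
    age_c = cov_frame.loc[cids, "age"]
    demo = {
        "age_welch": welch_t(age_p.mean(), age_p.std(ddof=1), len(age_p),
                             age_c.mean(), age_c.std(ddof=1), len(age_c)),
        "sex_chi2": chi2_2x2(int((cov_frame.loc[pids, "sex"] == "M").sum()),
                             int((cov_frame.loc[pids, "sex"] == "F").sum()),
                             int((cov_frame.loc[cids, "sex"] == "M").sum()),
                             int((cov_frame.loc[cids, "sex"] == "F").sum())),
        "education_mw": mann_whitney(cov_frame.loc[pids, "education"],
                                     cov_frame.loc[cids, "education"]),
    }

    # cognitive domains: z-score vs controls, residualize demographics
    domains = zscore_battery(cohort.battery, cids)
    resid = residualize(domains, _covariates(cov_frame, config.cognitive_covariates, ids))
    domain_tests = {}
    pvals = []
    for dom in domains.columns:
        mw = mann_whitney(domains.loc[pids, dom], domains.loc[cids, dom])
        domain_tests[dom] = mw
        pvals.append(mw["p"])
    fdr = bh_fdr(pvals)
    for i, dom in enumerate(domains.columns):
        domain_tests[dom]["p_fdr"] = float(fdr["adjusted"][i])

    # DMN damage-vs-disconnection models on patients
    dmn = cohort.atlas.parcels_in_network("DMN")
    y = resid.loc[pids, "Global"].to_numpy()
    integ = np.array([dmn_integrity(state["masked_sc"][sid], dmn) for sid in pids])
    local = np.array([dmn_local_lesion_load(cohort.lesions[sid], dmn) for sid in pids])
    total = np.array([cohort.lesions[sid].total_lesion_load for sid in pids])
    X = pd.DataFrame({"total_lesion_load": total, "dmn_local_lesion_load": local,
                      "dmn_wm_integrity": integ}, index=pids)
    ols = ols_fit(y, X, standardized=True)
    rlm = huber_rlm_fit(y, X)
    lesion_only = ols_fit(y, pd.DataFrame({"total_lesion_load": total}, index=pids),
                          standardized=True)
    avio.write_table(ols.as_frame(), out / "dmn_model_ols.tsv")
    avio.write_table(rlm.as_frame(), out / "dmn_model_rlm.tsv")

    # edgewise FC comparison + aggregate strengths
    edge_stats = {}
    if state["masked_fc"]:
        fc_p = [state["masked_fc"][sid] for sid in pids]
        fc_c = [state["masked_fc"][sid] for sid in cids]
        ew = edgewise_group_ttest(
            fc_p, fc_c,
            covariates=_covariates(cov_frame, ("mFD",), pids + cids),
            k=config.hyper_edge_k,
        )
        from .stats import aggregate_edge_strength

        hyper = {sid: aggregate_edge_strength(state["masked_fc"][sid], ew["hyper_edges"])
                 for sid in pids} if ew["hyper_edges"] else {}
        hypo = {sid: aggregate_edge_strength(state["masked_fc"][sid], ew["hypo_edges"])
                for sid in pids} if ew["hypo_edges"] else {}
        edge_stats = {
            "n_hyper": len(ew["hyper_edges"]),
            "n_hypo": len(ew["hypo_edges"]),
            "mean_abs_t": float(np.nanmean(np.abs(ew["tmat"]))),
        }
        if hyper:
            fit = ols_fit(y, pd.DataFrame({"hyper_strength": [hyper[s] for s in pids]}),
                          standardized=True)
            edge_stats["hyper_strength_model"] = fit["hyper_strength"]
        if hypo:
            fit = ols_fit(y, pd.DataFrame({"hypo_strength": [hypo[s] for s in pids]}),
                          standardized=True)
            edge_stats["hypo_strength_model"] = fit["hypo_strength"]

    # sensitivity sweep of the integrity effect
    def fit_at(density: float, cutoff: float) -> dict:
        vals = []
        for sid in pids:
            sc = apply_lesion_mask(cohort.sc[sid], cohort.lesions[sid], cutoff)
            sc = proportional_threshold(sc, density)
            vals.append(dmn_integrity(sc, dmn))
        res = ols_fit(y, pd.DataFrame({"dmn_wm_integrity": vals}, index=pids),
                      standardized=True)
        return res["dmn_wm_integrity"]

    sweep = sensitivity_sweep(fit_at, config.density_grid, config.lesion_cutoff_grid)
    avio.write_table(sweep.table, out / "sensitivity_sweep.tsv")

    report["stats"] = {
        "demographics": demo,
        "domain_tests": domain_tests,
        "dmn_model_ols": {t: ols[t] for t in ols.terms[1:]},
        "dmn_model_ols_adj_r2": ols.adj_r2,
        "dmn_model_rlm": {t: rlm[t] for t in rlm.terms[1:]},
        "lesion_load_only": lesion_only["total_lesion_load"],
        "edgewise": edge_stats,
        "sensitivity": {"robust": sweep.robust,
                        "degenerate_grid": sweep.degenerate_grid},
    }


_STAGE_FNS = {
    "synth": _stage_synth,
    "build": _stage_build,
    "metrics": _stage_metrics,
    "coupling": _stage_coupling,
    "ndm": _stage_ndm,
    "stats": _stage_stats,
}
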
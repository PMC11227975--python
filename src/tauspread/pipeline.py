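"""End-to-end orchestration: synthesize -> template -> tau -> spreading ->
clustering -> group statistics, from a single configuration with one seed.

Every stage writes its artifact under the output directory and the run
ends with a manifest (config hash, seeds, package versions, per-stage row
counts and file hashes).  Analyses that the study design stratifies by
amyloid status (spreading summary, mediation) are run pooled and per
stratum.  The pipeline never reads the generator's truth bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import group_stats as gs
from . import io as tio
from . import spreading as sp
from . import tau as td
from .config import DMN, PipelineConfig
from .connectome import (
    average_and_threshold,
    distance_to_epicentres,
    fisher_z_matrix,
    FCMatrix,
    to_distance,
)
from .errors import InputError, PipelineError
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("synthesize", "template", "tau", "spreading", "clustering", "group_stats")

REQUIRED_FILES = (
    "parcellation.tsv",
    "tau_scans.csv",
    "covariates.csv",
    "amyloid.csv",
    "fc_kind.txt",
)


def validate_inputs(input_dir) -> list[str]:
    """Schema checks on an input bundle; returns a list of violations."""
    root = Path(input_dir)
    violations = []
    for name in REQUIRED_FILES:
        if not (root / name).exists():
            violations.append(f"missing required file {name}")
    if violations:
        return violations
    parc = tio.read_parcellation(root / "parcellation.tsv")
    region_set = set(parc["region_id"])
    scans_df = pd.read_csv(root / "tau_scans.csv")
    extra = set(scans_df["region_id"]) - region_set
    if extra:
        violations.append(f"tau_scans.csv references unknown region ids {sorted(extra)[:5]}")
    for sid, g in scans_df.groupby("subject_id"):
        times = np.sort(g["scan_time_years"].unique())
        per_scan = g.groupby("scan_time_years")["region_id"].nunique()
        if len(times) < 2:
            violations.append(f"subject {sid}: fewer than 2 scan timepoints")
        if per_scan.nunique() > 1:
            violations.append(f"subject {sid}: inconsistent region coverage across scans")
    fc_dir = root / "subject_fc"
    if not fc_dir.is_dir():
        violations.append("missing subject_fc/ directory")
    else:
        n_regions = len(region_set)
        for path in sorted(fc_dir.glob("*.csv")):
            with open(path) as fh:
                n_rows = sum(1 for _ in fh) - 1
            if n_rows != n_regions:
                violations.append(
                    f"subject_fc/{path.name}: {n_rows} rows, expected {n_regions} regions"
                )
    amyloid = pd.read_csv(root / "amyloid.csv", index_col=0)
    amy_regions = {tio._coerce_id(c) for c in amyloid.columns}
    if amy_regions != region_set:
        violations.append("amyloid.csv region columns do not match the parcellation")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    if cfg.input_dir is not None and not Path(cfg.input_dir).is_dir():
        raise InputError(f"input directory {cfg.input_dir!r} does not exist")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": _jsonable(asdict(cfg)),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(asdict(cfg)), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": {},
    }
    failed = []
    state: dict = {}
    for stage in STAGES:
        try:
            info = _STAGE_FUNCS[stage](cfg, state, out)
            manifest["stages"][stage] = {"status": "ok", **info}
        except Exception as exc:  # record partial completion
            logger.exception("stage %s failed", stage)
            manifest["stages"][stage] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            failed.append(stage)
            break
    manifest["outputs"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(out.rglob("*.csv")) if p.is_file()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    if failed:
        raise PipelineError(f"stage(s) failed: {failed}; see manifest at {out / 'manifest.json'}")
    return manifest


def _stage_synthesize(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    if cfg.input_dir is not None:
        violations = validate_inputs(cfg.input_dir)
        if violations:
            raise InputError("input validation failed: " + "; ".join(violations[:10]))
        state["data_dir"] = Path(cfg.input_dir)
        return {"source": str(cfg.input_dir), "n_violations": 0}
    cohort = generate_cohort(cfg.cohort)
    data_dir = out / "data"
    tio.write_cohort(cohort, data_dir)
    state["data_dir"] = data_dir
    state["template_timeseries"] = cohort.template_timeseries
    return {"source": "synthetic", "n_subjects": cfg.cohort.n_subjects}


def _stage_template(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    data_dir = state["data_dir"]
    parc = tio.read_parcellation(data_dir / "parcellation.tsv")
    region_ids = list(parc["region_id"])
    ts_list = state.get("template_timeseries")
    if ts_list is None:
        ts_list = tio.read_template_timeseries(data_dir / "template_timeseries")
    fcs = [fisher_z_matrix(ts, region_ids, subject_id=f"T{i:03d}") for i, ts in enumerate(ts_list)]
    template = average_and_threshold(fcs, density=cfg.density)
    dist = to_distance(template, multi_hop=cfg.multi_hop)
    tio.write_matrix_csv(template.values, region_ids, out / "template.csv")
    tio.write_matrix_csv(dist.values, region_ids, out / "distance.csv")
    state.update(parcellation=parc, region_ids=region_ids, template=template, distance=dist)
    return {
        "density": template.realized_density(),
        "n_retained_pairs": template.n_retained_pairs,
    }


def _stage_tau(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    data_dir = state["data_dir"]
    scans = tio.read_tau_scans(data_dir / "tau_scans.csv")
    baseline = pd.DataFrame({s.subject_id: s.baseline() for s in scans}).T
    mixtures = td.fit_cohort_gmms(baseline)
    posteriors = td.posterior_probabilities(baseline, mixtures)
    cleaned = td.cleaned_suvr(baseline, posteriors)
    epicentres = {}
    for sid in cleaned.index:
        epicentres[sid] = td.select_epicentres(cleaned.loc[sid], k=cfg.k_epicentres, subject_id=sid)
    rates = td.estimate_rates(scans, mode=cfg.rate_mode)
    rates.rates.to_csv(out / "rates.csv", index_label="subject_id")
    with open(out / "epicentres.json", "w") as fh:
        json.dump(
            _jsonable(
                {sid: {"region_ids": e.region_ids, "values": e.values} for sid, e in epicentres.items()}
            ),
            fh,
            indent=1,
        )
    with open(out / "mixtures.json", "w") as fh:
        json.dump(
            {
                str(r): {
                    "weights": m.weights,
                    "means": m.means,
                    "sds": m.sds,
                    "degenerate": m.degenerate,
                }
                for r, m in mixtures.items()
            },
            fh,
            indent=1,
        )
    state.update(scans=scans, baseline=baseline, epicentres=epicentres, rates=rates)
    n_degenerate = sum(m.degenerate for m in mixtures.values())
    return {
        "n_subjects": len(scans),
        "rate_mode": rates.mode,
        "n_degenerate_regions": n_degenerate,
    }


def _stage_spreading(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    data_dir = state["data_dir"]
    dist = state["distance"]
    parc = state["parcellation"]
    net_of = parc.set_index("region_id")["network"]
    fc_kind = (data_dir / "fc_kind.txt").read_text().strip()
    fc_inputs = tio.read_subject_fc(data_dir / "subject_fc", fc_kind)
    amyloid = pd.read_csv(data_dir / "amyloid.csv", index_col=0)
    amyloid.columns = [tio._coerce_id(c) for c in amyloid.columns]
    rows, fc_rows = [], []
    dist_profiles = {}
    for sid, epi in state["epicentres"].items():
        profile = distance_to_epicentres(dist, epi.region_ids, agg=cfg.distance_agg)
        dist_profiles[sid] = profile
        res = sp.spreading_beta(state["rates"].rates.loc[sid], profile, subject_id=sid)
        arr = fc_inputs.get(sid)
        if arr is None:
            raise InputError(f"no FC input for subject {sid}")
        if fc_kind == "matrix":
            r = np.clip(arr, -0.999, 0.999)
            z = np.arctanh(r)
            np.fill_diagonal(z, 0.0)
            fcm = FCMatrix(values=z, region_ids=state["region_ids"], subject_id=sid)
        else:
            fcm = fisher_z_matrix(arr, state["region_ids"], subject_id=sid)
        fc2epi = sp.fc_to_epicentres(fcm, epi, net_of)
        epi_amyloid = sp.regional_mean(amyloid.loc[sid], epi.region_ids)
        rows.append(
            {
                "subject_id": sid,
                "beta": res.beta,
                "se": res.se,
                "p": res.p,
                "n_used": res.n_regions_used,
                "epi_amyloid": epi_amyloid,
                "epi_baseline_suvr": sp.regional_mean(state["baseline"].loc[sid], epi.region_ids),
                "mean_rate": float(state["rates"].rates.loc[sid].mean()),
            }
        )
        fc_rows.append(
            {"subject_id": sid, "global": fc2epi.global_fc, **fc2epi.per_network.to_dict()}
        )
    spread_df = pd.DataFrame(rows).set_index("subject_id")
    fc_df = pd.DataFrame(fc_rows).set_index("subject_id")
    spread_df.to_csv(out / "spreading.csv")
    fc_df.to_csv(out / "fc_to_epi.csv")

    covariates = pd.read_csv(data_dir / "covariates.csv", index_col=0)
    merged = spread_df.join(fc_df["global"].rename("fc_to_epi")).join(covariates)
    assoc = sp.association_model(
        merged, y="fc_to_epi", x="beta", covariates=["age", "sex", "education", "apoe4"]
    )
    mediation = {}
    strata = {"all": merged.index}
    strata["abeta_positive"] = merged.index[merged["abeta_status"] == 1]
    strata["abeta_negative"] = merged.index[merged["abeta_status"] == 0]
    for name, idx in strata.items():
        sub = merged.loc[idx]
        if len(sub) < 30:
            mediation[name] = {"skipped": f"only {len(sub)} subjects"}
            continue
        med = sp.mediate(
            sub["beta"],
            sub["epi_amyloid"],
            sub["fc_to_epi"],
            covariates=sub[["age", "sex"]],
            n_boot=cfg.n_boot,
            seed=cfg.seed,
        )
        mediation[name] = {
            "acme": med.acme,
            "ade": med.ade,
            "total_effect": med.total_effect,
            "proportion_mediated": med.proportion_mediated,
            "ci_proportion": list(med.ci_proportion),
            "p_acme": med.p_acme,
            "unstable": med.proportion_unstable,
            "n": med.n,
        }
    with open(out / "mediation.json", "w") as fh:
        json.dump(_jsonable(mediation), fh, indent=1)
    state.update(spread=spread_df, fc2epi=fc_df, merged=merged)
    return {
        "n_subjects": len(spread_df),
        "mean_beta": float(spread_df["beta"].mean()),
        "association_beta_fc": {"coef": assoc.coef, "p": assoc.p},
        "proportion_mediated_all": mediation["all"].get("proportion_mediated"),
    }


def _stage_clustering(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    fc_nets = state["fc2epi"].drop(columns=["global"])
    betas = state["spread"]["beta"]
    residuals, sds = cl.network_residuals(betas, fc_nets)
    profiles = cl.mismatch_profiles(
        residuals, sds, c=cfg.discretize_c, flip_signs=cfg.flip_discretize_signs
    )
    k, diagnostics = cl.choose_k(profiles, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1))
    assignment = cl.ward_cluster(profiles, k)
    if k == 4:
        assignment = cl.label_clusters(assignment, residuals, dmn_network=DMN)
    else:
        warnings.warn(f"silhouette selected k={k}; cluster labels left generic")
        assignment.labels = {int(c): f"cluster_{c}" for c in np.unique(assignment.cluster_index)}
    scores, loadings, evr = cl.pca_profiles(profiles)
    profiles.to_csv(out / "profiles.csv", index_label="subject_id")
    assignment.to_frame().to_csv(out / "clusters.csv", index=False)
    scores.iloc[:, :2].to_csv(out / "pca_scores.csv", index_label="subject_id")
    with open(out / "linkage.json", "w") as fh:
        json.dump(
            {
                "criterion": "ward (squared euclidean)",
                "k": k,
                "silhouette": assignment.silhouette,
                "diagnostics": diagnostics.reset_index().to_dict(orient="list"),
                "linkage": assignment.linkage_matrix.tolist(),
            },
            fh,
            indent=1,
        )
    state["clusters"] = assignment.to_frame().set_index("subject_id")["label"]
    state["residuals"] = residuals
    return {"k": k, "silhouette": float(assignment.silhouette), "labels": sorted(set(assignment.labels.values()))}


def _stage_group_stats(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    data_dir = state["data_dir"]
    covariates = pd.read_csv(data_dir / "covariates.csv", index_col=0)
    clusters = state["clusters"]
    merged = state["merged"]
    rows = []
    for outcome in ("epi_amyloid", "epi_baseline_suvr", "mean_rate", "beta"):
        comp = gs.ancova_compare(
            merged[outcome],
            clusters,
            covariates=covariates[["age", "sex", "education"]],
            adjust=cfg.adjust,
        )
        for _, r in comp.pairwise.iterrows():
            rows.append(
                {
                    "outcome": outcome,
                    "contrast": r["contrast"],
                    "estimate": r["estimate"],
                    "p_raw": r["p_raw"],
                    "p_adj": r["p_adj"],
                    "method": r["method"],
                    "f_overall": comp.f_stat,
                    "p_overall": comp.p_overall,
                }
            )
    pd.DataFrame(rows).to_csv(out / "comparisons.csv", index=False)
    table = pd.crosstab(covariates["apoe4"], clusters)
    chi2, dof, p_chi = gs.chi_square_freq(table.to_numpy())
    lme_info = None
    cog_path = data_dir / "cognition.csv"
    if cog_path.exists():
        cognition = pd.read_csv(cog_path)
        fit = gs.longitudinal_lme(
            cognition, clusters, covariates=covariates[["age", "sex", "education"]]
        )
        fit.fixed_effects.to_csv(out / "lme_fixed_effects.csv", index_label="term")
        lme_info = {
            "n_subjects": fit.n_subjects,
            "n_observations": fit.n_observations,
            "random_intercept_var": fit.random_intercept_var,
            "interaction_terms": {
                t: fit.fixed_effects.loc[t, "estimate"]
                for t in fit.fixed_effects.index
                if ":" in t
            },
        }
        with open(out / "lme_fit.json", "w") as fh:
            json.dump(_jsonable(lme_info), fh, indent=1)
    return {
        "n_comparisons": len(rows),
        "apoe_chi2": {"chi2": chi2, "dof": dof, "p": p_chi},
        "lme": lme_info is not None,
    }


_STAGE_FUNCS = {
    "synthesize": _stage_synthesize,
    "template": _stage_template,
    "tau": _stage_tau,
    "spreading": _stage_spreading,
    "clustering": _stage_clustering,
    "group_stats": _stage_group_stats,
}


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "tauspread": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
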
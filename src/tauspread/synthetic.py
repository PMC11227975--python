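"""Synthetic cohort generator.

Because the cohort the analysis was designed for is access-restricted,
every downstream stage is exercised on a fully synthetic cohort that
reproduces the *statistical structure* the analysis assumes:

* a modular 7-network connectome: template subjects' regional time-series
  are drawn from a block covariance with one correlation level inside
  network blocks and a lower one between them;
* bimodal cross-subject baseline SUVR in the regions surrounding a small
  pool of candidate epicentre seeds, so the per-region Gaussian-mixture
  positivity step has a genuine high-tau component to find;
* distance-dependent accumulation: each subject's regional tau rates are
  drawn so their population correlation with connectivity-based distance
  to the subject's planted epicentre set equals a configurable (negative)
  target;
* a planted linear mediation path (spreading -> epicentre amyloid -> FC
  to epicentres) with configurable (a, b, c') coefficients;
* four planted residual-pattern groups (canonical / resilient /
  susceptible / DMN-susceptible analogues) implemented as per-network
  FC-to-epicentre offsets.

The planted ground truth is returned (and written) separately from the
analysis inputs; no analysis stage reads it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortConfig
from .connectome import (
    DistanceConnectome,
    FCMatrix,
    average_and_threshold,
    distance_to_epicentres,
    fisher_z_matrix,
    to_distance,
)
from .errors import ConfigurationError
from .tau import RegionalScanSeries

logger = logging.getLogger(__name__)

ALL_COMPONENTS = ("template", "tau", "fc", "covariates")


@dataclass
class SyntheticCohort:
    """Bundle of generated inputs plus the separate planted-truth record."""

    config: CohortConfig
    parcellation: pd.DataFrame
    template_timeseries: list
    distance: DistanceConnectome
    mean_template_z: np.ndarray
    tau_scans: list = field(default_factory=list)
    subject_fc: dict = field(default_factory=dict)
    fc_kind: str = "timeseries"
    covariates: pd.DataFrame | None = None
    amyloid: pd.DataFrame | None = None
    cognition: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    @property
    def region_ids(self) -> list:
        return list(self.parcellation["region_id"])

    def baseline_suvr(self) -> pd.DataFrame:
        rows = {s.subject_id: s.baseline() for s in self.tau_scans}
        return pd.DataFrame(rows).T


def make_parcellation(cfg: CohortConfig) -> pd.DataFrame:
    """Region metadata: 1-based ids, network label, alternating hemisphere."""
    records = []
    rid = 1
    for net, size in zip(cfg.network_names, cfg.network_sizes):
        for i in range(size):
            records.append(
                {"region_id": rid, "network": net, "hemisphere": "L" if i % 2 == 0 else "R"}
            )
            rid += 1
    return pd.DataFrame(records)


def _block_covariance(cfg: CohortConfig) -> np.ndarray:
    w, b = cfg.within_network_corr, cfg.between_network_corr
    n = cfg.n_regions
    cov = np.full((n, n), b)
    start = 0
    for size in cfg.network_sizes:
        cov[start : start + size, start : start + size] = w
        start += size
    np.fill_diagonal(cov, 1.0)
    return cov


def generate_template_timeseries(cfg: CohortConfig, rng: np.random.Generator | None = None) -> list:
    """Regional time-series for the normative template cohort.

    Frames are i.i.d. draws from a zero-mean Gaussian whose population
    correlation is ``within_network_corr`` inside network blocks and
    ``between_network_corr`` elsewhere; the finite number of frames
    provides natural per-subject sampling noise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cov = _block_covariance(cfg)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            "implied template covariance is not positive definite; adjust "
            f"within_network_corr={cfg.within_network_corr} / "
            f"between_network_corr={cfg.between_network_corr}"
        ) from exc
    out = []
    for _ in range(cfg.n_template_subjects):
        z = rng.standard_normal((cfg.n_regions, cfg.n_timeseries_frames))
        out.append(chol @ z)
    return out


def _seed_candidates(cfg: CohortConfig, parcellation: pd.DataFrame) -> list:
    """Candidate epicentre seed regions, spread across distinct networks.

    One region (the middle of its block) per network, cycling through
    limbic, default-mode and visual cortex first — emulating the medial
    temporal / posterior origins of tau pathology while guaranteeing that
    each lifted region stays bimodal across subjects.
    """
    preferred = ["Limbic", "Default", "Vis", "SomMot", "DorsAttn", "SalVentAttn", "Cont"]
    nets = [n for n in preferred if n in set(parcellation["network"])]
    cands = []
    for i in range(cfg.n_seed_candidates):
        net = nets[i % len(nets)]
        block = parcellation.loc[parcellation["network"] == net, "region_id"].to_numpy()
        cands.append(int(block[len(block) // 2]))
    return cands


def _planted_epicentres(dist: DistanceConnectome, seed_region: int, k: int) -> list:
    """The k regions nearest the seed (ties to the lowest id), seed included."""
    ids = np.asarray(dist.region_ids)
    col = dist.values[:, list(ids).index(seed_region)]
    col = np.where(np.isfinite(col), col, np.inf)
    order = np.lexsort((np.arange(col.size), col))
    return sorted(int(ids[i]) for i in order[:k])


def generate_tau_scans(
    cfg: CohortConfig,
    dist: DistanceConnectome,
    truth: dict,
    rng: np.random.Generator,
) -> list[RegionalScanSeries]:
    """Longitudinal tau-PET scans with planted distance-dependent accumulation.

    Baseline SUVR is a truncated-normal background plus an abnormal lift
    of ``suvr_lift * exp(-d/lift_decay_scale)`` on the subject's planted
    epicentre set (d = distance to the seed), which makes those regions
    bimodal across subjects.  Regional yearly rates are drawn so that,
    across non-epicentre regions, their correlation with distance to the
    epicentre set equals the subject's planted value.  Scan times follow
    the configured follow-up distribution.
    """
    import warnings as _warnings

    if cfg.planted_spread_corr >= 0:
        _warnings.warn(
            "planted_spread_corr >= 0: connectivity-mediated spreading is "
            "expected to produce negative rate-distance correlations"
        )
    region_ids = list(dist.region_ids)
    ids_arr = np.asarray(region_ids)
    sd = cfg.noise_sds
    mean_fu, sd_fu = cfg.followup_years_mean_sd
    scans = []
    for sid, sub in truth["subjects"].items():
        seed = sub["seed_region"]
        epi = sub["epicentre_ids"]
        rho = sub["planted_rho"]
        seed_idx = region_ids.index(seed)
        d_seed = dist.values[:, seed_idx]
        epi_mask = np.isin(ids_arr, epi)
        lift = np.where(
            epi_mask,
            cfg.suvr_lift * np.exp(-np.nan_to_num(d_seed, nan=np.inf) / cfg.lift_decay_scale),
            0.0,
        )
        baseline = np.maximum(rng.normal(cfg.suvr_background_mean, sd["baseline"], len(region_ids)), 0.8)
        baseline = baseline + lift
        # rates: planted correlation with distance-to-epicentres over non-epicentre regions
        profile = distance_to_epicentres(dist, epi)
        prof = profile.to_numpy()
        prof = np.where(np.isfinite(prof), prof, np.nanmean(prof))
        z_d = (prof - prof.mean()) / prof.std()
        eps = rng.standard_normal(z_d.size)
        rate_z = rho * z_d + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        rates = np.empty(len(region_ids))
        rates[~epi_mask] = cfg.rate_mean + cfg.rate_sd * rate_z
        # epicentre regions themselves accumulate fast (they are not part of
        # the spreading regression, which uses non-epicentre regions only)
        rates[epi_mask] = cfg.rate_mean + cfg.rate_sd * (
            1.5 + 0.3 * rng.standard_normal(int(epi_mask.sum()))
        )
        lo, hi = cfg.scans_per_subject
        n_scans = int(rng.integers(lo, hi + 1))
        total = float(np.clip(rng.normal(mean_fu, sd_fu), 0.5, 6.0))
        times = np.linspace(0.0, total, n_scans)
        suvr = baseline[None, :] + rates[None, :] * times[:, None]
        suvr = suvr + rng.normal(0.0, sd["scan"], suvr.shape)
        suvr = np.maximum(suvr, 0.05)
        scans.append(
            RegionalScanSeries(subject_id=sid, times=times, suvr=suvr, region_ids=region_ids)
        )
        sub["planted_rates"] = rates.tolist()
    return scans


def _factor_loadings(
    t: np.ndarray, c: np.ndarray, a0: float
) -> tuple[np.ndarray, int]:
    """Per-region loadings on the epicentre factor hitting target correlations.

    With base correlation c between a region and the epicentres and factor
    loading a0 on the epicentre side, a region loading alpha yields
    ``corr = (c + a0*alpha) / sqrt((1 + alpha^2)(1 + a0^2))``.  Solving for
    alpha is a quadratic; targets beyond the attainable bound
    ``sqrt(c^2 + a0^2) / sqrt(1 + a0^2)`` are clamped (count returned).
    """
    k2 = 1.0 + a0**2
    t_max = np.sqrt((c**2 + a0**2) / k2)
    n_clamped = int(np.sum(np.abs(t) > 0.99 * t_max))
    t = np.clip(t, -0.99 * t_max, 0.99 * t_max)
    A = a0**2 - t**2 * k2
    B = 2.0 * a0 * c
    C = c**2 - t**2 * k2
    disc = np.maximum(B**2 - 4.0 * A * C, 0.0)
    sq = np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        roots = np.stack([(-B + sq) / (2 * A), (-B - sq) / (2 * A)])
    # valid root: sign of (c + a0*alpha) must match the target's sign
    resid = np.abs(np.sign(c + a0 * roots) - np.sign(t))
    alpha = np.where(resid[0] <= resid[1], roots[0], roots[1])
    alpha = np.where(np.abs(A) < 1e-12, -C / np.where(B == 0, 1.0, B), alpha)
    return alpha, n_clamped


def generate_subject_fc(
    cfg: CohortConfig,
    cohort: "SyntheticCohort",
    rng: np.random.Generator,
) -> dict:
    """Subject FC inputs carrying the planted mediation and group structure.

    Each subject's expected FC-to-epicentre value per network is
    ``c0 - c'*s - b*m + group offset + noise`` where s is the subject's
    spread strength and m their (already drawn) epicentre amyloid — i.e.
    stronger spreading and higher epicentre amyloid both lower FC to the
    epicentres.  The target is realized through a latent epicentre factor
    added to the modular base covariance: epicentre regions load on the
    factor with a fixed weight and every non-epicentre region's loading is
    solved so its epicentre correlation matches the network's target.
    The resulting covariance is valid by construction and is emitted
    either as the exact correlation matrix or as time-series sampled from
    it.
    """
    a, b, c_prime = cfg.mediation_coeffs
    c0 = cfg.fc_base + b * 1.4  # typical FC-to-epicentre ~ fc_base at average amyloid
    a0 = cfg.fc_factor_loading
    sd = cfg.noise_sds
    parc = cohort.parcellation
    region_ids = cohort.region_ids
    n = len(region_ids)
    idx_of = {rid: i for i, rid in enumerate(region_ids)}
    net_of = parc.set_index("region_id")["network"]
    base = _block_covariance(cfg)
    chol0 = np.linalg.cholesky(base)
    out = {}
    for sid, sub in cohort.truth["subjects"].items():
        s = sub["spread_strength"]
        m = sub["target_epi_amyloid"]
        offsets = dict(zip(cfg.network_names, cfg.group_offsets[sub["cluster"]]))
        epi = sub["epicentre_ids"]
        epi_idx = np.array([idx_of[e] for e in epi])
        epi_mask = np.zeros(n, dtype=bool)
        epi_mask[epi_idx] = True
        targets = {}
        t_region = np.zeros(n)
        for net in cfg.network_names:
            members = np.array(
                [idx_of[r] for r in region_ids if net_of[r] == net and not epi_mask[idx_of[r]]]
            )
            if members.size == 0:
                continue
            y_net = c0 - c_prime * s - b * m + offsets[net] + rng.normal(0.0, sd["fc"])
            targets[net] = float(y_net)
            t_region[members] = np.tanh(y_net)  # target on the correlation scale
        sub["fc_targets"] = targets
        c_base = base[:, epi_idx].mean(axis=1)
        alpha = np.zeros(n)
        alpha[epi_mask] = a0
        non_epi = ~epi_mask
        alpha[non_epi], n_clamped = _factor_loadings(
            t_region[non_epi], c_base[non_epi], a0
        )
        if n_clamped:
            logger.debug("subject %s: %d region targets at the attainable bound", sid, n_clamped)
        if cfg.fc_output == "matrix":
            cov = base + np.outer(alpha, alpha)
            d = np.sqrt(np.diag(cov))
            r = cov / np.outer(d, d)
            jitter = rng.normal(0.0, sd["fc_pair"] / 10.0, (n, n))
            r = np.clip(r + jitter + jitter.T, -0.99, 0.99)
            np.fill_diagonal(r, 1.0)
            out[sid] = r
        else:
            white = rng.standard_normal((n, cfg.n_timeseries_frames))
            factor = rng.standard_normal(cfg.n_timeseries_frames)
            out[sid] = chol0 @ white + alpha[:, None] * factor[None, :]
    return out


def _generate_covariates(cfg: CohortConfig, truth: dict, rng: np.random.Generator) -> pd.DataFrame:
    subjects = list(truth["subjects"])
    n = len(subjects)
    status = np.array([truth["subjects"][s]["abeta_positive"] for s in subjects], dtype=int)
    age = rng.normal(70.0, 6.3, n)
    sex = (rng.random(n) < 0.56).astype(int)  # 1 = female
    education = np.clip(rng.normal(16.3, 2.5, n), 10, 22)
    apoe_p = np.where(status == 1, 55 / 94, 30 / 117)
    apoe4 = (rng.random(n) < apoe_p).astype(int)
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "age": age,
            "sex": sex,
            "education": education,
            "apoe4": apoe4,
            "abeta_status": status,
        }
    ).set_index("subject_id")


def _generate_amyloid(
    cfg: CohortConfig, truth: dict, region_ids: list, rng: np.random.Generator
) -> pd.DataFrame:
    """Regional amyloid maps whose epicentre mean equals the planted mediator."""
    a = cfg.mediation_coeffs[0]
    sd = cfg.noise_sds
    rows = {}
    for sid, sub in truth["subjects"].items():
        base = 1.2 + 0.4 * sub["abeta_positive"]
        m_i = base + a * sub["spread_strength"] + rng.normal(0.0, sd["amyloid"])
        values = base + rng.normal(0.0, sd["amyloid_region"], len(region_ids))
        epi_mask = np.isin(np.asarray(region_ids), sub["epicentre_ids"])
        jitter = rng.normal(0.0, sd["amyloid_region"], int(epi_mask.sum()))
        values[epi_mask] = m_i + (jitter - jitter.mean())  # exact planted epicentre mean
        sub["target_epi_amyloid"] = float(m_i)
        rows[sid] = values
    return pd.DataFrame(rows, index=region_ids).T


def _generate_cognition(cfg: CohortConfig, truth: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Linear cognitive trajectories with cluster-specific slopes."""
    sd = cfg.noise_sds
    records = []
    for sid, sub in truth["subjects"].items():
        intercept = rng.normal(0.4, sd["cognition_intercept"]) - 0.2 * sub["abeta_positive"]
        slope = cfg.cognition_slopes[sub["cluster"]] + rng.normal(0.0, 0.03)
        sub["cognition_slope"] = float(slope)
        for t in range(cfg.n_cognition_visits):
            records.append(
                {
                    "subject_id": sid,
                    "time_years": float(t),
                    "score": intercept + slope * t + rng.normal(0.0, sd["cognition_visit"]),
                }
            )
    return pd.DataFrame(records)


def generate_cohort(cfg: CohortConfig, components=ALL_COMPONENTS) -> SyntheticCohort:
    """Generate a full synthetic cohort from a single seed.

    ``components`` can restrict generation (e.g. omit "fc" for analyses
    that only need the tau side); the template/distance stage always runs
    because the tau mechanism is defined on the connectome.
    """
    rng = np.random.default_rng(cfg.seed)
    parcellation = make_parcellation(cfg)
    region_ids = list(parcellation["region_id"])
    template_ts = generate_template_timeseries(cfg, rng)
    fcs = [
        fisher_z_matrix(ts, region_ids, subject_id=f"T{i:03d}")
        for i, ts in enumerate(template_ts)
    ]
    mean_z = np.mean([m.values for m in fcs], axis=0)
    template = average_and_threshold(fcs, density=cfg.fc_density)
    dist = to_distance(template)

    n = cfg.n_subjects
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    n_pos = int(round(cfg.frac_abeta_positive * n))
    status = np.zeros(n, dtype=int)
    status[:n_pos] = 1
    rng.shuffle(status)
    candidates = _seed_candidates(cfg, parcellation)
    group_labels = list(cfg.group_offsets)
    truth = {
        "seed": cfg.seed,
        "mediation_coeffs": list(cfg.mediation_coeffs),
        "planted_spread_corr": cfg.planted_spread_corr,
        "seed_candidates": candidates,
        "proportion_mediated": _planted_proportion(cfg.mediation_coeffs),
        "subjects": {},
    }
    for i, sid in enumerate(subjects):
        s_i = float(rng.standard_normal())
        # clip keeps rho a valid correlation; rarely active at the defaults
        rho = float(np.clip(cfg.planted_spread_corr - cfg.spread_corr_sd * s_i, -1.0, 1.0))
        seed_region = int(rng.choice(candidates))
        truth["subjects"][sid] = {
            "abeta_positive": int(status[i]),
            "cluster": group_labels[int(rng.integers(len(group_labels)))],
            "spread_strength": s_i,
            "planted_rho": rho,
            "seed_region": seed_region,
            "epicentre_ids": _planted_epicentres(dist, seed_region, cfg.epicentre_size),
        }

    cohort = SyntheticCohort(
        config=cfg,
        parcellation=parcellation,
        template_timeseries=template_ts,
        distance=dist,
        mean_template_z=mean_z,
        truth=truth,
        fc_kind=cfg.fc_output,
    )
    if "covariates" in components:
        cohort.covariates = _generate_covariates(cfg, truth, rng)
    cohort.amyloid = _generate_amyloid(cfg, truth, region_ids, rng)
    if "tau" in components:
        cohort.tau_scans = generate_tau_scans(cfg, dist, truth, rng)
    if "fc" in components:
        cohort.subject_fc = generate_subject_fc(cfg, cohort, rng)
    if "covariates" in components:
        cohort.cognition = _generate_cognition(cfg, truth, rng)
    return cohort


def _planted_proportion(coeffs) -> float:
    a, b, c_prime = coeffs
    return a * b / (a * b + c_prime)


# ---------------------------------------------------------------------------
# light-weight subject-level samplers (same planted models, no imaging layer)
# ---------------------------------------------------------------------------

def plant_mediation_sample(
    n: int,
    coeffs=None,
    noise_sds=(0.4, 0.3),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (x, m, y) from the planted linear mediation model.

    ``m = a x + e_m``, ``y = c' x + b m + e_y``; the population proportion
    mediated is ``a b / (a b + c')`` (0.25 at the default coefficients).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a, b, c_prime = coeffs if coeffs is not None else CohortConfig().mediation_coeffs
    sd_m, sd_y = noise_sds
    x = rng.standard_normal(n)
    m = a * x + sd_m * rng.standard_normal(n)
    y = c_prime * x + b * m + sd_y * rng.standard_normal(n)
    return x, m, y


def plant_mismatch_sample(
    n: int,
    cfg: CohortConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Subject-level (beta, per-network FC-to-epicentre, group label) sample.

    Uses the same planted model as the full generator — spread strength
    drives both the spreading beta and (through the mediation path) the
    FC-to-epicentre level, on top of which the per-network group offsets
    and FC noise are added — but skips the imaging layer, for studies of
    the residual-clustering stages in isolation.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a, b, c_prime = cfg.mediation_coeffs
    c0 = 0.3 + b * 1.4
    sd = cfg.noise_sds
    labels = list(cfg.group_offsets)
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    s = rng.standard_normal(n)
    beta = np.clip(cfg.planted_spread_corr - cfg.spread_corr_sd * s, -0.95, 0.2)
    m = 1.4 + a * s + sd["amyloid"] * rng.standard_normal(n)
    cluster = rng.integers(len(labels), size=n)
    fc = {}
    for j, net in enumerate(cfg.network_names):
        offs = np.array([cfg.group_offsets[labels[c]][j] for c in cluster])
        fc[net] = c0 - c_prime * s - b * m + offs + sd["fc"] * rng.standard_normal(n)
    index = pd.Index(subjects, name="subject_id")
    return (
        pd.Series(beta, index=index, name="beta"),
        pd.DataFrame(fc, index=index),
        pd.Series([labels[c] for c in cluster], index=index, name="cluster"),
    )
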
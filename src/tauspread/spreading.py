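"""Connectivity-mediated spreading statistics and amyloid mediation.

The central quantity is the per-subject *spreading beta*: the standardized
regression coefficient of regional tau accumulation rate on
connectivity-based distance to that subject's epicentres, computed across
non-epicentre regions.  Both variables are z-scored, so with no further
covariate the beta equals the Pearson correlation; negative values mean
faster accumulation in regions functionally closer to the epicentres,
i.e. connectivity-mediated spreading.

Also provided: FC-to-epicentre summaries (mean Fisher-Z connectivity of
non-epicentre regions to the epicentre set, globally and per network),
covariate-adjusted association models, and a linear product-of-coefficients
mediation analysis with case-resampling bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import FCMatrix
from .errors import InputError
from .tau import EpicentreSet

logger = logging.getLogger(__name__)


@dataclass
class SpreadingResult:
    subject_id: str
    beta: float
    se: float
    p: float
    n_regions_used: int
    n_dropped: int = 0
    beta_euclid_adjusted: float | None = None


@dataclass
class FCtoEpicentre:
    subject_id: str
    global_fc: float
    per_network: pd.Series
    per_region: pd.Series


@dataclass
class AssociationResult:
    coef: float
    se: float
    p: float
    n: int


@dataclass
class MediationResult:
    acme: float
    ade: float
    total_effect: float
    proportion_mediated: float
    ci_acme: tuple[float, float]
    ci_ade: tuple[float, float]
    ci_total: tuple[float, float]
    ci_proportion: tuple[float, float]
    p_acme: float
    proportion_unstable: bool
    n: int
    n_boot: int
    seed: int | None


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise InputError("zero variance; cannot standardize")
    return (v - v.mean()) / sd


def spreading_beta(
    rates: pd.Series,
    dist: pd.Series,
    euclid: pd.Series | None = None,
    subject_id: str = "",
) -> SpreadingResult:
    """Standardized beta of tau rate-of-change on distance-to-epicentres.

    Inputs are aligned on region id over the non-epicentre regions;
    regions with missing distance are dropped (and counted).  Both sides
    are z-scored, so without the optional Euclidean-distance covariate the
    beta equals the Pearson correlation.
    """
    df = pd.DataFrame({"rate": rates, "dist": dist})
    if euclid is not None:
        df["euclid"] = euclid
    df = df.dropna()
    n_dropped = len(rates) - len(df)
    if len(df) < 10:
        raise InputError(f"only {len(df)} usable regions (need >=10)")
    y = _zscore(df["rate"].to_numpy())
    x = _zscore(df["dist"].to_numpy())
    n = len(df)
    if euclid is not None:
        X = np.column_stack([np.ones(n), x, _zscore(df["euclid"].to_numpy())])
    else:
        X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    from scipy.stats import t as t_dist

    p = float(2 * t_dist.sf(abs(beta / se), dof)) if se > 0 else 0.0
    return SpreadingResult(
        subject_id=subject_id,
        beta=beta,
        se=se,
        p=p,
        n_regions_used=n,
        n_dropped=n_dropped,
        beta_euclid_adjusted=beta if euclid is not None else None,
    )


def group_spreading_beta(
    rates: pd.DataFrame,
    dist_profiles: pd.DataFrame,
    mode: str = "averaged",
) -> SpreadingResult:
    """Group-level spreading beta across subjects.

    mode "averaged" (default): average rates and distance profiles over
    subjects region-wise, then regress once.  mode "pooled": stack every
    (subject, region) pair into a single regression.  When all subjects
    share identical rates and distances both modes coincide with the
    subject-level statistic.
    """
    common = rates.columns.intersection(dist_profiles.columns)
    if mode == "averaged":
        return spreading_beta(rates[common].mean(axis=0), dist_profiles[common].mean(axis=0), subject_id="group")
    if mode == "pooled":
        r = rates[common].to_numpy().ravel()
        d = dist_profiles[common].to_numpy().ravel()
        return spreading_beta(
            pd.Series(r), pd.Series(d), subject_id="group-pooled"
        )
    raise InputError(f"unknown group mode {mode!r}")


def fc_to_epicentres(
    subject_fc: FCMatrix,
    epi: EpicentreSet,
    network_labels: pd.Series,
) -> FCtoEpicentre:
    """Mean Fisher-Z connectivity of non-epicentre regions to the epicentres.

    per_region(r) is the mean Z over the (r, epicentre) pairs; the global
    value is the mean over all non-epicentre regions, and per-network
    values restrict that mean to each network's non-epicentre regions
    (NaN, with a log message, for a network with none).
    """
    ids = subject_fc.region_ids
    index = {rid: i for i, rid in enumerate(ids)}
    missing = [e for e in epi.region_ids if e not in index]
    if missing:
        raise InputError(f"epicentre ids missing from FC matrix: {missing}")
    epi_set = set(epi.region_ids)
    non_epi = [rid for rid in ids if rid not in epi_set]
    rows = [index[r] for r in non_epi]
    cols = [index[e] for e in epi.region_ids]
    per_region = pd.Series(
        subject_fc.values[np.ix_(rows, cols)].mean(axis=1),
        index=pd.Index(non_epi, name="region_id"),
        name="fc_to_epicentres",
    )
    global_fc = float(per_region.mean())
    nets = network_labels.reindex(per_region.index)
    per_network = per_region.groupby(nets).mean()
    all_networks = pd.unique(network_labels)
    per_network = per_network.reindex(all_networks)
    empty = per_network.index[per_network.isna()]
    if len(empty):
        logger.info(
            "subject %s: network(s) %s have no non-epicentre region", epi.subject_id, list(empty)
        )
    return FCtoEpicentre(
        subject_id=epi.subject_id,
        global_fc=global_fc,
        per_network=per_network,
        per_region=per_region,
    )


def regional_mean(values: pd.Series, region_set) -> float:
    """Arithmetic mean of a regional map over a region set (e.g. epicentre amyloid)."""
    region_set = list(region_set)
    if not region_set:
        raise InputError("empty region set")
    missing = [r for r in region_set if r not in values.index]
    if missing:
        raise InputError(f"region id(s) not in map: {missing}")
    return float(values.loc[region_set].mean())


def association_model(
    data: pd.DataFrame,
    y: str,
    x: str,
    covariates: list[str] | None = None,
) -> AssociationResult:
    """Covariate-adjusted linear association, reported as a standardized coefficient.

    Continuous variables are z-scored; 0/1 indicators (sex, APOE e4
    carriage) are left on their natural scale so the coefficient for a
    continuous predictor remains an SD-per-SD effect.
    """
    covariates = list(covariates or [])
    cols = [y, x] + covariates
    df = data[cols].dropna()
    n = len(df)
    p = len(cols) - 1
    if n <= p + 2:
        raise InputError(f"too few complete cases (n={n}) for {p} predictors")
    mat = {}
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        if df[c].nunique() > 2:
            sd = v.std(ddof=1)
            if sd == 0:
                raise InputError(f"constant column {c!r}")
            v = (v - v.mean()) / sd
        mat[c] = v
    X = np.column_stack([np.ones(n)] + [mat[c] for c in cols[1:]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending set: columns whose removal restores full rank
        guilty = []
        for j, c in enumerate(cols[1:], start=1):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                guilty.append(c)
        raise InputError(f"perfectly collinear predictors: {guilty or cols[1:]}")
    import statsmodels.api as sm

    fit = sm.OLS(mat[y], X).fit()
    return AssociationResult(
        coef=float(fit.params[1]), se=float(fit.bse[1]), p=float(fit.pvalues[1]), n=n
    )


def _batched_lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve OLS normal equations for a batch of design matrices.

    X: (B, n, p), y: (B, n) -> coefficients (B, p).
    """
    G = np.einsum("bni,bnj->bij", X, X)
    h = np.einsum("bni,bn->bi", X, y)
    return np.linalg.solve(G, h[..., None])[..., 0]


def mediate(
    x,
    m,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MediationResult:
    """Linear product-of-coefficients mediation with bootstrap CIs.

    Fits ``m ~ x + cov`` (path a), ``y ~ x + m + cov`` (paths b and c')
    and ``y ~ x + cov`` (total effect).  ACME = a*b, ADE = c'; in nested
    linear models ACME + ADE equals the total effect exactly.  The
    proportion mediated is the signed ratio ACME/total, flagged unstable
    when |total| < 2 SE(total).  Percentile confidence intervals come from
    case-resampling bootstrap (seeded, hence reproducible).
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    ok = np.isfinite(x) & np.isfinite(m) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, m, y, cov = x[ok], m[ok], y[ok], cov[ok]
    n = x.size
    if n < 30:
        raise InputError(f"mediation needs >=30 complete cases, got {n}")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if v.std() == 0:
            raise InputError(f"degenerate variance in {name}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; confidence intervals will be unstable")

    ones = np.ones((n, 1))
    Xa = np.hstack([ones, x[:, None], cov])  # m ~ x + cov
    Xb = np.hstack([ones, x[:, None], m[:, None], cov])  # y ~ x + m + cov
    coef_a, *_ = np.linalg.lstsq(Xa, m, rcond=None)
    coef_b, *_ = np.linalg.lstsq(Xb, y, rcond=None)
    coef_c, *_ = np.linalg.lstsq(Xa, y, rcond=None)  # same design, outcome y
    a = float(coef_a[1])
    b = float(coef_b[2])
    c_prime = float(coef_b[1])
    total = float(coef_c[1])
    acme = a * b
    resid_c = y - Xa @ coef_c
    dof = n - Xa.shape[1]
    se_total = float(
        np.sqrt((resid_c @ resid_c) / dof * np.linalg.inv(Xa.T @ Xa)[1, 1])
    )
    unstable = abs(total) < 2 * se_total
    proportion = acme / total if total != 0 else np.nan

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Xa_b, Xb_b = Xa[idx], Xb[idx]
    m_b, y_b = m[idx], y[idx]
    ca = _batched_lstsq(Xa_b, m_b)
    cb = _batched_lstsq(Xb_b, y_b)
    cc = _batched_lstsq(Xa_b, y_b)
    acme_b = ca[:, 1] * cb[:, 2]
    ade_b = cb[:, 1]
    total_b = cc[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_b = np.where(total_b != 0, acme_b / total_b, np.nan)

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)

    def _ci(v):
        return (float(np.nanpercentile(v, lo)), float(np.nanpercentile(v, hi)))

    p_acme = float(2 * min(np.mean(acme_b <= 0), np.mean(acme_b >= 0)))
    p_acme = min(max(p_acme, 1.0 / n_boot), 1.0)
    return MediationResult(
        acme=acme,
        ade=c_prime,
        total_effect=total,
        proportion_mediated=float(proportion),
        ci_acme=_ci(acme_b),
        ci_ade=_ci(ade_b),
        ci_total=_ci(total_b),
        ci_proportion=_ci(prop_b),
        p_acme=p_acme,
        proportion_unstable=bool(unstable),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )
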
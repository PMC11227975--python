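"""Regional tau-PET dynamics: accumulation rates, mixture-based tau
positivity, cleaned SUVR maps and subject-specific epicentres.

Tau positivity is estimated per region by fitting a two-component Gaussian
mixture to the cross-subject distribution of baseline SUVR; the posterior
probability of the high-mean ("abnormal") component serves as a
probabilistic tau-positivity measure, avoiding a fixed SUVR cut-off.
Multiplying the posterior by the raw SUVR gives a *cleaned* SUVR map from
which each subject's epicentres — the 10 regions with the greatest
probability-weighted signal — are selected.

Accumulation rates (SUVR/year) come either from per-subject least-squares
slopes or, by default, from region-wise linear mixed-effects models with a
random intercept and slope per subject, whose empirical-Bayes slopes
shrink noisy individual estimates toward the population trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import InputError

logger = logging.getLogger(__name__)

GMM_MIN_N = 20  # below this, a region is flagged degenerate rather than fitted
GMM_MAX_ITER = 500
GMM_TOL = 1e-6
#: a mixture is degenerate when the component means are closer than this
#: multiple of the pooled SD, or when the high component nearly vanishes.
#: EM on a single Gaussian splits it into overlapping halves roughly 1.2-1.6
#: pooled SDs apart, while a genuine abnormal tau component sits several SDs
#: above background, so 2.0 separates the two regimes.
GMM_MIN_SEPARATION = 2.0
GMM_MIN_HIGH_WEIGHT = 0.01


@dataclass
class RegionalScanSeries:
    """Longitudinal tau-PET scans for one subject.

    ``times`` are years since baseline (strictly increasing, >=2 scans);
    ``suvr`` has one row per scan, one column per region (all positive).
    """

    subject_id: str
    times: np.ndarray
    suvr: np.ndarray
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.suvr = np.asarray(self.suvr, dtype=float)
        if self.times.size < 2:
            raise InputError(f"subject {self.subject_id}: need >=2 scans")
        if not np.all(np.diff(self.times) > 0):
            raise InputError(f"subject {self.subject_id}: scan times not strictly increasing")
        if self.suvr.shape[0] != self.times.size:
            raise InputError(f"subject {self.subject_id}: one SUVR row per scan required")
        if not np.all(self.suvr > 0):
            raise InputError(f"subject {self.subject_id}: SUVR values must be positive")
        if not self.region_ids:
            self.region_ids = list(range(1, self.suvr.shape[1] + 1))

    @property
    def n_scans(self) -> int:
        return int(self.times.size)

    def baseline(self) -> pd.Series:
        return pd.Series(self.suvr[0], index=self.region_ids)


@dataclass
class RegionMixture:
    """Two-component univariate Gaussian mixture for one region.

    Components are ordered low/high by mean.  ``degenerate`` marks regions
    where no meaningful high-tau component exists; their posteriors are 0.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    degenerate: bool = False
    n: int = 0


@dataclass
class EpicentreSet:
    subject_id: str
    region_ids: list
    values: np.ndarray  # probability-weighted SUVR of the selected regions


@dataclass
class TauRateMaps:
    """Per-subject regional accumulation rates (SUVR/year)."""

    rates: pd.DataFrame  # subjects x regions
    mode: str  # "subject-slope" or "mixed"


def fit_region_gmm(baseline_values: np.ndarray) -> RegionMixture:
    """Fit a two-component Gaussian mixture to one region's baseline SUVR.

    EM with deterministic initialization (components seeded at the 25th and
    75th percentiles, equal weights), components ordered by mean.  With
    fewer than 20 values, or when the fitted components are inseparable
    (mean difference below ``GMM_MIN_SEPARATION`` pooled SDs) or the high
    component has weight < 0.01, the region is flagged degenerate and all
    posteriors are 0.
    """
    x = np.asarray(baseline_values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite baseline SUVR values")
    mu, sd = float(np.mean(x)), float(np.std(x))
    if x.size < GMM_MIN_N:
        return RegionMixture((1.0, 0.0), (mu, mu), (max(sd, 1e-6),) * 2, degenerate=True, n=x.size)
    q25, q75 = np.percentile(x, [25, 75])
    var0 = max(sd**2 / 4.0, 1e-8)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        max_iter=GMM_MAX_ITER,
        tol=GMM_TOL,
        reg_covar=1e-9,
        weights_init=np.array([0.5, 0.5]),
        means_init=np.array([[q25], [q75]]),
        precisions_init=np.array([[[1.0 / var0]], [[1.0 / var0]]]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    w = gm.weights_
    order = np.argsort(means)
    means, sds, w = means[order], sds[order], w[order]
    pooled_sd = float(np.sqrt(w[0] * sds[0] ** 2 + w[1] * sds[1] ** 2))
    degenerate = (means[1] - means[0]) < GMM_MIN_SEPARATION * pooled_sd or w[1] < GMM_MIN_HIGH_WEIGHT
    return RegionMixture(
        weights=(float(w[0]), float(w[1])),
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        degenerate=bool(degenerate),
        n=x.size,
    )


def tau_probability(mix: RegionMixture, suvr) -> np.ndarray | float:
    """Posterior probability of the high-tau component at the given SUVR.

    Returns 0 for degenerate mixtures.  The posterior is nondecreasing in
    SUVR between the two component means (and everywhere when the
    component variances are equal).
    """
    x = np.asarray(suvr, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if mix.degenerate:
        out = np.zeros_like(x)
        return float(out[0]) if scalar else out
    (wl, wh), (ml, mh), (sl, sh) = mix.weights, mix.means, mix.sds
    log_l = np.log(max(wl, 1e-300)) + norm.logpdf(x, ml, sl)
    log_h = np.log(max(wh, 1e-300)) + norm.logpdf(x, mh, sh)
    post = 1.0 / (1.0 + np.exp(np.clip(log_l - log_h, -700, 700)))
    return float(post[0]) if scalar else post


def fit_cohort_gmms(baseline: pd.DataFrame) -> dict:
    """Fit one region mixture per column of a subjects x regions baseline table."""
    return {region: fit_region_gmm(baseline[region].to_numpy()) for region in baseline.columns}


def posterior_probabilities(baseline: pd.DataFrame, mixtures: dict) -> pd.DataFrame:
    """Tau-positivity posterior for every subject and region."""
    out = {}
    for region in baseline.columns:
        out[region] = tau_probability(mixtures[region], baseline[region].to_numpy())
    return pd.DataFrame(out, index=baseline.index)


def cleaned_suvr(suvr_map: pd.DataFrame, posteriors: pd.DataFrame) -> pd.DataFrame:
    """Probability-weighted (cleaned) SUVR: elementwise posterior x SUVR."""
    if suvr_map.shape != posteriors.shape or list(suvr_map.columns) != list(posteriors.columns):
        raise InputError("SUVR map and posterior table are not aligned")
    return suvr_map * posteriors.to_numpy()


def select_epicentres(cleaned: pd.Series, k: int = 10, subject_id: str = "") -> EpicentreSet:
    """Select the k regions with the greatest cleaned SUVR.

    Ties at rank k are broken toward the lowest region index so the
    selection is deterministic.  An all-zero cleaned map means no abnormal
    tau signal anywhere and is an error.
    """
    values = cleaned.to_numpy(dtype=float)
    if values.size < k:
        raise InputError(f"need at least {k} regions, got {values.size}")
    if np.all(values == 0):
        raise InputError(f"no abnormal tau signal for subject {subject_id!r}")
    # stable sort on (-value, position): lowest index wins among ties
    order = np.lexsort((np.arange(values.size), -values))
    top = order[:k]
    top = np.sort(top)  # report in region order
    ids = [cleaned.index[i] for i in top]
    return EpicentreSet(subject_id=subject_id, region_ids=ids, values=values[top])


def _subject_fit(series: RegionalScanSeries) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares (intercepts, slopes) of SUVR on time, all regions at once."""
    t = series.times
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, series.suvr, rcond=None)
    return coef[0], coef[1]


def estimate_rates(cohort: list[RegionalScanSeries], mode: str = "mixed") -> TauRateMaps:
    """Estimate regional tau accumulation rates (SUVR/year) for a cohort.

    mode "subject-slope": independent OLS slope per subject and region.
    mode "mixed" (default): per region, a linear mixed model
    ``SUVR ~ time`` with random intercept and slope per subject; a
    subject's rate is the fixed slope plus their predicted random slope.
    Regions where the mixed fit fails or is singular fall back to
    subject slopes with a logged warning.
    """
    if mode not in ("subject-slope", "mixed"):
        raise InputError(f"unknown rate mode {mode!r}")
    usable = []
    for s in cohort:
        if s.n_scans < 2:
            logger.warning("subject %s has <2 scans; excluded from rate estimation", s.subject_id)
            continue
        usable.append(s)
    if not usable:
        raise InputError("no subject with >=2 scans")
    region_ids = usable[0].region_ids
    for s in usable[1:]:
        if s.region_ids != region_ids:
            raise InputError("inconsistent region sets across subjects")
    subject_ids = [s.subject_id for s in usable]
    fits = [_subject_fit(s) for s in usable]
    slopes = np.vstack([f[1] for f in fits])
    intercepts = np.vstack([f[0] for f in fits])
    if mode == "subject-slope":
        rates = pd.DataFrame(slopes, index=subject_ids, columns=region_ids)
        return TauRateMaps(rates=rates, mode=mode)

    import statsmodels.api as sm  # deferred: heavy import

    n_sub = len(usable)
    times = np.concatenate([s.times for s in usable])
    groups = np.concatenate([np.full(s.n_scans, i) for i, s in enumerate(usable)])
    exog = np.column_stack([np.ones_like(times), times])
    rates = np.empty((n_sub, len(region_ids)))
    n_fallback = 0
    for j, region in enumerate(region_ids):
        endog = np.concatenate([s.suvr[:, j] for s in usable])
        within_resid = np.concatenate(
            [s.suvr[:, j] - (intercepts[i, j] + slopes[i, j] * s.times) for i, s in enumerate(usable)]
        )
        if np.max(np.abs(within_resid)) < 1e-8 * max(1.0, float(np.abs(endog).max())):
            # per-subject fits are exact: residual variance is degenerate and
            # the mixed model is unidentified, but the subject slopes are the
            # truth already
            rates[:, j] = slopes[:, j]
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog)
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            re = fit.random_effects
            rates[:, j] = fit.fe_params[1] + np.array(
                [np.asarray(re[i])[1] for i in range(n_sub)]
            )
            if not np.all(np.isfinite(rates[:, j])):
                raise np.linalg.LinAlgError("non-finite mixed-model rates")
        except Exception:  # singular fit, convergence failure
            rates[:, j] = slopes[:, j]
            n_fallback += 1
    if n_fallback:
        logger.warning(
            "mixed-model rate estimation fell back to subject slopes for %d region(s)",
            n_fallback,
        )
    return TauRateMaps(rates=pd.DataFrame(rates, index=subject_ids, columns=region_ids), mode=mode)
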
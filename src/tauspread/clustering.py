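"""Mismatch profiling and susceptibility/resilience subtyping.

For each of the seven cortical networks, a robust (Tukey bisquare)
regression of network FC-to-epicentres on the subject's spreading beta
yields per-subject residuals: how much more or less functional
disconnection a subject shows than their level of tau spreading predicts.
Residuals beyond 0.7 residual SD are discretized (positive residual ->
-1, negative -> +1, following the original sign convention; configurable),
giving a 7-value mismatch profile per subject.  Profiles are clustered
with Ward's agglomerative hierarchical clustering; the number of clusters
is picked by silhouette (elbow diagnostics reported), and clusters are
labelled canonical / resilient / susceptible / DMN-susceptible from their
mean *raw* residual patterns, so labels do not depend on the discretization
sign convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import InputError

logger = logging.getLogger(__name__)

BISQUARE_C = 4.685  # Tukey tuning constant, 95% Gaussian efficiency
DISCRETIZE_C = 0.7  # residual threshold in units of residual SD

CLUSTER_LABELS = ("canonical", "resilient", "susceptible", "dmn-susceptible")


@dataclass
class RobustFit:
    slope: float
    intercept: float
    residuals: np.ndarray
    residual_sd: float
    n_iter: int


@dataclass
class ClusterAssignment:
    subject_ids: list
    cluster_index: np.ndarray  # 1-based cluster indices
    labels: dict = field(default_factory=dict)  # cluster index -> name
    linkage_matrix: np.ndarray | None = None
    k: int = 0
    silhouette: float = float("nan")

    def label_of(self, subject_pos: int) -> str:
        return self.labels.get(int(self.cluster_index[subject_pos]), f"cluster_{self.cluster_index[subject_pos]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "cluster": self.cluster_index,
                "label": [self.label_of(i) for i in range(len(self.subject_ids))],
            }
        )


def robust_regress(x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> RobustFit:
    """Bisquare-weighted robust line fit of y on x (IRLS, MAD scale).

    Tukey's biweight with tuning constant 4.685 downweights gross outliers
    to zero.  The reported residual SD is the classical (ddof=1) SD of the
    final residuals, the scale used downstream for discretization.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y length mismatch")
    if x.size < 10:
        raise InputError(f"robust regression needs >=10 subjects, got {x.size}")
    if np.ptp(x) == 0:
        raise InputError("constant predictor in robust regression")
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(x), x])
    ols_coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ ols_coef
    scale = np.median(np.abs(ols_resid - np.median(ols_resid)))
    if scale < 1e-10 * max(1.0, float(np.abs(y).max())):
        # (near-)perfect linear fit: the MAD scale degenerates, IRLS has
        # nothing to reweight — the OLS line is the robust line
        return RobustFit(
            slope=float(ols_coef[1]),
            intercept=float(ols_coef[0]),
            residuals=ols_resid,
            residual_sd=float(np.std(ols_resid, ddof=1)),
            n_iter=0,
        )
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    fit = model.fit(maxiter=max_iter, tol=tol, scale_est="mad")
    deviances = list(fit.fit_history.get("deviance", []))
    n_iter = len(deviances)
    if n_iter >= max_iter and len(deviances) >= 2:
        # practical criterion: IRLS can dither in the last digits of the
        # deviance long after the parameters have settled
        rel = abs(deviances[-1] - deviances[-2]) / max(abs(deviances[-2]), 1e-12)
        if rel > 1e-6:
            raise RuntimeError(
                f"robust regression did not converge in {max_iter} iterations; "
                f"last deviances {deviances[-5:]}"
            )
    resid = y - X @ fit.params
    return RobustFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        residuals=resid,
        residual_sd=float(np.std(resid, ddof=1)),
        n_iter=n_iter,
    )


def discretize(
    residuals: np.ndarray,
    residual_sd: float,
    c: float = DISCRETIZE_C,
    flip_signs: bool = False,
) -> np.ndarray:
    """Trichotomize residuals at +/- c * SD into {-1, 0, +1}.

    The default mapping follows the original convention: a residual
    *exceeding* +c SD (strictly) maps to -1, one below -c SD maps to +1,
    anything within (inclusive of the boundary) maps to 0.
    ``flip_signs=True`` inverts the mapping; the choice is logged.
    """
    residuals = np.asarray(residuals, dtype=float)
    if not np.isnan(residual_sd) and residual_sd < 0:
        raise InputError("negative residual SD")
    if residual_sd == 0:
        warnings.warn("zero residual SD; all discretized values set to 0")
        return np.zeros(residuals.shape, dtype=int)
    # missing residuals (e.g. a network fully inside the epicentre set) are
    # neutral: comparisons in NaN-aware form below leave them at 0
    out = np.zeros(residuals.shape, dtype=int)
    out[residuals > c * residual_sd] = -1
    out[residuals < -c * residual_sd] = 1
    if flip_signs:
        logger.info("discretization sign convention flipped (positive residual -> +1)")
        out = -out
    return out


def network_residuals(
    betas: pd.Series,
    fc_per_network: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-network robust-regression residuals of FC-to-epicentres on beta.

    Returns (residual table subjects x networks, residual SD per network).
    """
    common = betas.index.intersection(fc_per_network.index)
    betas = betas.loc[common]
    fc_per_network = fc_per_network.loc[common]
    resid = pd.DataFrame(np.nan, index=common, columns=fc_per_network.columns, dtype=float)
    sds = {}
    for net in fc_per_network.columns:
        y = fc_per_network[net]
        ok = y.notna() & betas.notna()
        if ok.sum() < 10:
            logger.warning(
                "network %s: only %d subjects with FC-to-epicentre values; residuals left missing",
                net,
                int(ok.sum()),
            )
            sds[net] = np.nan
            continue
        fit = robust_regress(betas[ok].to_numpy(), y[ok].to_numpy())
        resid.loc[ok, net] = fit.residuals
        sds[net] = fit.residual_sd
    return resid, pd.Series(sds, name="residual_sd")


def mismatch_profiles(
    residuals: pd.DataFrame,
    residual_sds: pd.Series,
    c: float = DISCRETIZE_C,
    flip_signs: bool = False,
) -> pd.DataFrame:
    """Discretized {-1, 0, 1} mismatch profile per subject and network."""
    out = {
        net: discretize(residuals[net].to_numpy(), float(residual_sds[net]), c=c, flip_signs=flip_signs)
        for net in residuals.columns
    }
    return pd.DataFrame(out, index=residuals.index)


def ward_cluster(profiles: pd.DataFrame, k: int) -> ClusterAssignment:
    """Ward agglomerative clustering of mismatch profiles, cut at k clusters.

    Euclidean distances on the 7-value profiles, Ward.D2-style criterion
    (scipy's implementation); subjects enter in index order, which fixes
    the tie-break deterministically.
    """
    if k < 2:
        raise InputError(f"k must be >=2, got {k}")
    if len(profiles) < k:
        raise InputError(f"cannot form {k} clusters from {len(profiles)} subjects")
    X = profiles.to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    idx = fcluster(Z, t=k, criterion="maxclust")
    sil = float("nan")
    if 2 <= k <= len(profiles) - 1 and len(np.unique(idx)) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sil = float(silhouette_score(X, idx))
    return ClusterAssignment(
        subject_ids=list(profiles.index),
        cluster_index=idx,
        linkage_matrix=Z,
        k=int(len(np.unique(idx))),
        silhouette=sil,
    )


def choose_k(
    profiles: pd.DataFrame,
    k_range=range(2, 9),
    min_cluster_frac: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Pick the number of clusters by mean silhouette over a k range.

    A value of k is admissible only when the cut actually yields k
    clusters and every cluster holds at least ``min_cluster_frac`` of the
    subjects — on discretized profiles, larger k otherwise splits off
    near-duplicate satellite patterns of a handful of subjects for
    marginal silhouette gains, which is not a subtype.  Among admissible
    k the mean silhouette is maximized (ties to the smallest k).  The
    within-cluster sum of squares (elbow curve) is returned as a
    diagnostic; when the elbow and silhouette disagree the silhouette
    wins (logged).  Structureless data (max silhouette < 0.25) triggers a
    warning.
    """
    k_range = list(k_range)
    if len(profiles) < max(k_range) + 1:
        raise InputError(
            f"need >= {max(k_range) + 1} subjects to scan k up to {max(k_range)}"
        )
    X = profiles.to_numpy(dtype=float)
    if np.all(np.ptp(X, axis=0) == 0):
        raise InputError("no cluster structure: all profiles identical")
    min_size = max(2, int(np.ceil(min_cluster_frac * len(profiles))))
    rows = []
    for k in k_range:
        assign = ward_cluster(profiles, k)
        sizes = np.bincount(assign.cluster_index)[1:]
        admissible = assign.k == k and sizes.min() >= min_size
        wss = 0.0
        for c in np.unique(assign.cluster_index):
            pts = X[assign.cluster_index == c]
            wss += float(((pts - pts.mean(axis=0)) ** 2).sum())
        rows.append(
            {"k": k, "silhouette": assign.silhouette, "wss": wss, "admissible": admissible}
        )
    diag = pd.DataFrame(rows).set_index("k")
    eligible = diag[diag["admissible"]] if diag["admissible"].any() else diag
    best_k = int(eligible["silhouette"].idxmax())
    if diag["silhouette"].max() < 0.25:
        warnings.warn(
            f"weak cluster structure: max silhouette "
            f"{diag['silhouette'].max():.3f} < 0.25"
        )
    # elbow diagnostic: largest second difference of the WSS curve
    if len(diag) >= 3:
        wss = diag["wss"].to_numpy()
        elbow_k = int(diag.index[np.argmax(np.diff(wss, 2)) + 1])
        if elbow_k != best_k:
            logger.info("elbow suggests k=%d, silhouette k=%d; silhouette wins", elbow_k, best_k)
    return best_k, diag


def pca_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of centred mismatch profiles (scores, loadings, variance fractions)."""
    if len(profiles) < 3:
        raise InputError("PCA needs >=3 subjects")
    X = profiles.to_numpy(dtype=float)
    if np.all(np.ptp(X, axis=0) == 0):
        raise InputError("zero-variance profiles; nothing to decompose")
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(scores, index=profiles.index, columns=comp_names)
    loadings = pd.DataFrame(pca.components_, index=comp_names, columns=profiles.columns)
    return scores, loadings, pca.explained_variance_ratio_


def label_clusters(
    assignment: ClusterAssignment,
    raw_residuals: pd.DataFrame,
    dmn_network,
) -> ClusterAssignment:
    """Name clusters from their mean raw residual patterns.

    canonical: smallest mean |residual| across networks (disconnection
    commensurate with spreading).  resilient: of the rest, the most
    positive overall mean (less disconnection than expected).  Of the two
    remaining, the cluster whose DMN residual is markedly below its other
    networks (by > 0.5 pooled residual SD) is dmn-susceptible, the other
    susceptible.  With k != 4 or an unresolvable pattern, generic
    ``cluster_i`` labels are kept and a warning is emitted.
    """
    ks = np.unique(assignment.cluster_index)
    means = raw_residuals.groupby(assignment.cluster_index).mean()
    if len(ks) != 4:
        warnings.warn(f"expected 4 clusters for labelling, got {len(ks)}; using generic labels")
        assignment.labels = {int(c): f"cluster_{c}" for c in ks}
        return assignment
    if dmn_network not in raw_residuals.columns:
        raise InputError(f"DMN network {dmn_network!r} not among residual columns")
    pooled_sd = float(raw_residuals.stack().std(ddof=1))
    abs_mean = means.abs().mean(axis=1)
    canonical = int(abs_mean.idxmin())
    rest = [int(c) for c in ks if c != canonical]
    overall = means.mean(axis=1)
    resilient = int(overall.loc[rest].idxmax())
    last_two = [c for c in rest if c != resilient]
    non_dmn = [c for c in raw_residuals.columns if c != dmn_network]

    def dmn_gap(c):
        return float(means.loc[c, dmn_network] - means.loc[c, non_dmn].mean())

    gaps = {c: dmn_gap(c) for c in last_two}
    concentrated = [c for c, g in gaps.items() if g < -0.5 * pooled_sd]
    labels = {canonical: "canonical", resilient: "resilient"}
    if len(concentrated) == 1:
        dmn_c = concentrated[0]
        labels[dmn_c] = "dmn-susceptible"
        labels[[c for c in last_two if c != dmn_c][0]] = "susceptible"
    else:
        warnings.warn(
            "could not resolve susceptible vs DMN-susceptible pattern; using generic labels"
        )
        for c in last_two:
            labels[c] = f"cluster_{c}"
    assignment.labels = labels
    return assignment
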
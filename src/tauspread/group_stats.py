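"""Between-cluster comparisons: covariate-adjusted ANOVA, multiplicity
correction, genotype frequency tests and longitudinal mixed-effects
cognition models.

Outcomes (epicentre amyloid burden, baseline tau, accumulation rate,
cognitive scores) are compared across the susceptibility clusters with a
linear model ``outcome ~ cluster + covariates`` (age, sex, education by
default); pairwise contrasts reuse the full-model residual variance.
Pairwise p-values are adjusted with Benjamini-Hochberg (default) or
Bonferroni.  APOE e4 carrier frequencies are compared with Pearson
chi-square tests.  Longitudinal cognition is modelled with a linear mixed
model with a random intercept per subject and a cluster-by-time
interaction, whose coefficients quantify cluster-specific extra decline in
outcome units per year.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


@dataclass
class GroupComparison:
    outcome: str
    f_stat: float
    p_overall: float
    pairwise: pd.DataFrame  # contrast, estimate, p_raw, p_adj, method
    covariates: list = field(default_factory=list)
    n: int = 0
    excluded_clusters: list = field(default_factory=list)


@dataclass
class LongitudinalFit:
    fixed_effects: pd.DataFrame  # estimate, se, p per term
    random_intercept_var: float
    n_subjects: int
    n_observations: int
    converged: bool = True


def ancova_compare(
    outcome: pd.Series,
    clusters: pd.Series,
    covariates: pd.DataFrame | None = None,
    adjust: str = "bh",
) -> GroupComparison:
    """Covariate-adjusted comparison of an outcome across clusters.

    Fits ``outcome ~ C(cluster) + covariates`` by OLS, reports the overall
    cluster F-test and all pairwise cluster contrasts (tested against the
    full-model residual variance).  Clusters with fewer than 3 subjects
    are excluded with a warning.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"__y": outcome, "__g": clusters})
    cov_names: list[str] = []
    if covariates is not None:
        cov_names = list(covariates.columns)
        df = df.join(covariates)
    df = df.dropna()
    sizes = df["__g"].value_counts()
    small = sorted(sizes.index[sizes < 3].tolist())
    if small:
        warnings.warn(f"cluster(s) {small} have <3 subjects; excluded from comparison")
        df = df[~df["__g"].isin(small)]
    groups = sorted(df["__g"].unique())
    if len(groups) < 2:
        raise InputError("need >=2 clusters with >=3 subjects each")
    n = len(df)
    # dummy coding, first group as reference
    dummies = pd.get_dummies(df["__g"], prefix="g", drop_first=True).astype(float)
    X = np.column_stack(
        [np.ones(n), dummies.to_numpy()]
        + [df[c].to_numpy(dtype=float) for c in cov_names]
    )
    y = df["__y"].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    k_dum = dummies.shape[1]
    R = np.zeros((k_dum, X.shape[1]))
    R[:, 1 : 1 + k_dum] = np.eye(k_dum)
    ftest = fit.f_test(R)
    # pairwise contrasts on group means (covariate-adjusted)
    rows = []
    coef_by_group = {groups[0]: 0.0}
    for j, g in enumerate(groups[1:], start=1):
        coef_by_group[g] = float(fit.params[j])
    for ga, gb in itertools.combinations(groups, 2):
        contrast = np.zeros(X.shape[1])
        for j, g in enumerate(groups[1:], start=1):
            contrast[j] = (1.0 if g == gb else 0.0) - (1.0 if g == ga else 0.0)
        tt = fit.t_test(contrast)
        rows.append(
            {
                "contrast": f"{gb} - {ga}",
                "estimate": float(np.atleast_1d(tt.effect)[0]),
                "p_raw": float(np.atleast_1d(tt.pvalue.item() if hasattr(tt.pvalue, "item") else tt.pvalue)[0]),
            }
        )
    pairwise = pd.DataFrame(rows)
    adj, _ = adjust_pvalues(pairwise["p_raw"].tolist(), method=adjust)
    pairwise["p_adj"] = adj
    pairwise["method"] = adjust
    return GroupComparison(
        outcome=str(outcome.name or "outcome"),
        f_stat=float(ftest.fvalue),
        p_overall=float(ftest.pvalue),
        pairwise=pairwise,
        covariates=cov_names,
        n=n,
        excluded_clusters=small,
    )


def adjust_pvalues(p, method: str = "bh", q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-testing adjustment: BH step-up (FDR) or Bonferroni.

    Returns (adjusted p-values, boolean rejection mask at level q).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise InputError(f"unknown adjustment method {method!r} (use 'bh' or 'bonferroni')")
    reject, p_adj, *_ = multipletests(p, alpha=q, method=key)
    return p_adj, reject


def chi_square_freq(contingency) -> tuple[float, int, float]:
    """Pearson chi-square test (no continuity correction) on a counts table.

    Warns when any expected count is below 5.
    """
    table = np.asarray(contingency)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise InputError("contingency table must hold nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InputError("zero-margin row or column in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            f"expected count(s) below 5 (min {expected.min():.2f}); "
            "chi-square approximation may be poor"
        )
    return float(chi2), int(dof), float(p)


def longitudinal_lme(
    cognition: pd.DataFrame,
    clusters: pd.Series,
    covariates: pd.DataFrame | None = None,
    subject_col: str = "subject_id",
    time_col: str = "time_years",
    score_col: str = "score",
) -> LongitudinalFit:
    """Longitudinal cognition model with cluster-by-time interaction.

    Fits ``score ~ baseline_score + time * C(cluster) + covariates`` with
    a random intercept per subject.  The ``time:cluster`` coefficients are
    each cluster's extra annual change relative to the reference cluster
    (outcome units / year).  If the random-intercept variance cannot be
    estimated (e.g. a single subject), falls back to pooled OLS with a
    warning.
    """
    import statsmodels.formula.api as smf

    df = cognition[[subject_col, time_col, score_col]].copy()
    base = (
        df.sort_values(time_col)
        .groupby(subject_col)[score_col]
        .first()
        .rename("baseline_score")
    )
    df = df.join(base, on=subject_col)
    df = df.join(clusters.rename("cluster"), on=subject_col)
    cov_names: list[str] = []
    if covariates is not None:
        cov_names = list(covariates.columns)
        df = df.join(covariates, on=subject_col)
    df = df.dropna()
    n_obs_per = df.groupby(subject_col).size()
    if (n_obs_per >= 2).sum() == 0:
        raise InputError("no longitudinal information: every subject has a single timepoint")
    if (n_obs_per >= 2).mean() < 0.5:
        warnings.warn("fewer than half the subjects have repeated observations")
    rhs = f"baseline_score + {time_col} * C(cluster)"
    for c in cov_names:
        rhs += f" + {c}"
    formula = f"{score_col} ~ {rhs}"
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df[subject_col])
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        re_var = float(np.asarray(fit.cov_re)[0, 0])
        params, bse, pvals = fit.fe_params, fit.bse_fe, fit.pvalues
        terms = list(params.index)
    except Exception:
        warnings.warn("mixed model degenerate; falling back to pooled OLS fixed effects")
        converged = False
        import statsmodels.formula.api as smf2

        fit = smf2.ols(formula, data=df).fit()
        re_var = 0.0
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        terms = list(params.index)
    fe = pd.DataFrame(
        {
            "estimate": [float(params[t]) for t in terms],
            "se": [float(bse[t]) for t in terms],
            "p": [float(pvals[t]) for t in terms],
        },
        index=terms,
    )
    return LongitudinalFit(
        fixed_effects=fe,
        random_intercept_var=re_var,
        n_subjects=int(df[subject_col].nunique()),
        n_observations=int(len(df)),
        converged=converged,
    )
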
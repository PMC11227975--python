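"""Robust residuals, discretization, Ward clustering and cluster labelling."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tauspread import (
    CohortConfig,
    choose_k,
    discretize,
    label_clusters,
    mismatch_profiles,
    network_residuals,
    pca_profiles,
    plant_mismatch_sample,
    robust_regress,
    ward_cluster,
)
from tauspread.errors import InputError

NETS = ["Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default"]


class TestRobustRegress:
    def test_perfect_line(self, rng):
        x = rng.uniform(-1, 1, 30)
        y = 2.0 * x + 1.0
        fit = robust_regress(x, y)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_outlier_resistance_vs_ols(self, rng):
        x = rng.uniform(-1, 1, 60)
        y = 1.5 * x + rng.normal(0, 0.05, 60)
        y[7] += 10 * y.std()  # gross outlier
        robust = robust_regress(x, y).slope
        ols = np.polyfit(x, y, 1)[0]
        assert abs(robust - 1.5) < abs(ols - 1.5)

    def test_constant_predictor(self):
        with pytest.raises(InputError, match="constant"):
            robust_regress(np.ones(20), np.arange(20.0))

    def test_too_few_subjects(self):
        with pytest.raises(InputError, match=">=10"):
            robust_regress(np.arange(5.0), np.arange(5.0))


class TestDiscretize:
    def test_sign_convention(self):
        # positive residuals beyond the cut mark *less* disconnection -> -1
        out = discretize(np.array([0.71, -0.71, 0.69, -0.69, 0.0]), residual_sd=1.0, c=0.7)
        assert list(out) == [-1, 1, 0, 0, 0]

    def test_boundary_is_strict(self):
        out = discretize(np.array([0.7, -0.7]), residual_sd=1.0, c=0.7)
        assert list(out) == [0, 0]

    def test_flip_signs(self):
        out = discretize(np.array([2.0, -2.0]), residual_sd=1.0, flip_signs=True)
        assert list(out) == [1, -1]

    def test_zero_sd_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero residual SD"):
            out = discretize(np.array([1.0, -1.0]), residual_sd=0.0)
        assert list(out) == [0, 0]

    def test_scale_invariance_through_robust_regression(self, rng):
        x = rng.uniform(-1, 1, 80)
        y = 0.5 * x + rng.normal(0, 0.2, 80)
        fit = robust_regress(x, y)
        fit_scaled = robust_regress(x, 3.7 * y)
        a = discretize(fit.residuals, fit.residual_sd)
        b = discretize(fit_scaled.residuals, fit_scaled.residual_sd)
        assert np.array_equal(a, b)


def _profiles(rows, index=None):
    return pd.DataFrame(rows, columns=NETS, index=index or range(len(rows)))


def _ward_wss(X, labels):
    return sum(
        float(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum())
        for c in np.unique(labels)
    )


def _min_wss_partition(X, k):
    """Exhaustive minimum within-cluster sum of squares over all k-partitions."""
    n = len(X)
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        best = min(best, _ward_wss(X, np.asarray(assignment)))
    return best


class TestWardCluster:
    def test_two_separated_blobs(self):
        rows = [[0] * 7, [0] * 7, [0, 0, 0, 0, 0, 0, 1], [1] * 7, [1] * 7, [1, 1, 1, 1, 1, 1, 0]]
        assign = ward_cluster(_profiles(rows), k=2)
        idx = assign.cluster_index
        assert len(set(idx[:3])) == 1 and len(set(idx[3:])) == 1 and idx[0] != idx[3]

    def test_k_equals_n_gives_singletons(self, rng):
        prof = _profiles(rng.integers(-1, 2, (5, 7)) + rng.normal(0, 0.01, (5, 7)))
        assign = ward_cluster(prof, k=5)
        assert len(np.unique(assign.cluster_index)) == 5

    def test_permutation_invariance(self, rng):
        rows = rng.integers(-1, 2, (12, 7)).astype(float)
        prof = _profiles(rows, index=[f"S{i:02d}" for i in range(12)])
        perm = rng.permutation(12)
        a = ward_cluster(prof, k=3)
        b = ward_cluster(prof.iloc[perm], k=3)
        pred_a = pd.Series(a.cluster_index, index=a.subject_ids)
        pred_b = pd.Series(b.cluster_index, index=b.subject_ids)
        assert adjusted_rand_score(pred_a.sort_index(), pred_b.sort_index()) == pytest.approx(1.0)

    def test_invalid_k(self, rng):
        prof = _profiles(rng.integers(-1, 2, (6, 7)))
        with pytest.raises(InputError):
            ward_cluster(prof, k=1)
        with pytest.raises(InputError):
            ward_cluster(prof, k=9)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("k", [2, 3])
    def test_achieves_minimum_ward_objective_on_small_inputs(self, seed, k):
        # structured draws: two to three planted patterns plus sign flips,
        # the regime the pipeline operates in
        rng = np.random.default_rng(seed)
        protos = rng.integers(-1, 2, (k, 7)).astype(float)
        X = protos[rng.integers(0, k, 8)]
        flips = rng.random(X.shape) < 0.1
        X = np.where(flips, X - np.sign(X + 0.5), X)
        assign = ward_cluster(_profiles(X), k=k)
        achieved = _ward_wss(X, assign.cluster_index)
        assert achieved == pytest.approx(_min_wss_partition(X, k), abs=1e-9)


class TestChooseK:
    def test_four_planted_groups(self):
        betas, fcn, labels = plant_mismatch_sample(211, CohortConfig(seed=0), rng=0)
        resid, sds = network_residuals(betas, fcn)
        profiles = mismatch_profiles(resid, sds)
        k, diag = choose_k(profiles)
        assert k == 4
        assert set(diag.columns) >= {"silhouette", "wss"}

    def test_two_planted_groups(self):
        cfg = CohortConfig(
            seed=0,
            group_offsets={
                "canonical": (0.0,) * 7,
                "susceptible": (-0.6,) * 7,
            },
        )
        betas, fcn, labels = plant_mismatch_sample(180, cfg, rng=3)
        resid, sds = network_residuals(betas, fcn)
        profiles = mismatch_profiles(resid, sds)
        k, _ = choose_k(profiles)
        assert k == 2

    def test_structureless_noise_warns(self, rng):
        prof = pd.DataFrame(rng.standard_normal((120, 7)), columns=NETS)
        with pytest.warns(UserWarning, match="weak cluster structure"):
            k, diag = choose_k(prof)
        assert diag["silhouette"].max() < 0.25

    def test_identical_profiles_error(self):
        prof = pd.DataFrame(np.ones((30, 7)), columns=NETS)
        with pytest.raises(InputError, match="no cluster structure"):
            choose_k(prof)


class TestPCA:
    def test_orthonormal_loadings_and_variance_conservation(self, rng):
        prof = pd.DataFrame(rng.integers(-1, 2, (40, 7)).astype(float), columns=NETS)
        scores, loadings, evr = pca_profiles(prof)
        L = loadings.to_numpy()
        assert np.allclose(L @ L.T, np.eye(L.shape[0]), atol=1e-10)
        assert evr.sum() == pytest.approx(1.0, abs=1e-10)

    def test_rank_one_profiles(self, rng):
        base = np.array([1.0, -1, 0, 1, 0, -1, 1])
        prof = pd.DataFrame(np.outer(rng.standard_normal(25), base), columns=NETS)
        _, _, evr = pca_profiles(prof)
        assert evr[0] >= 0.999

    def test_zero_variance_error(self):
        with pytest.raises(InputError):
            pca_profiles(pd.DataFrame(np.zeros((10, 7)), columns=NETS))


class TestLabelClusters:
    def _assignment(self, labels):
        from tauspread.clustering import ClusterAssignment

        return ClusterAssignment(
            subject_ids=list(range(len(labels))), cluster_index=np.asarray(labels), k=len(set(labels))
        )

    def _residuals(self, cluster_means, labels, sd=0.02, seed=0):
        rng = np.random.default_rng(seed)
        rows = [cluster_means[c] + rng.normal(0, sd, 7) for c in labels]
        return pd.DataFrame(rows, columns=NETS)

    def test_labels_follow_mean_residual_patterns(self):
        means = {
            1: np.zeros(7),                                  # canonical
            2: np.full(7, 0.5),                              # resilient
            3: np.array([-0.5] * 6 + [0.0]),                 # susceptible
            4: np.array([0.0] * 6 + [-0.6]),                 # DMN-concentrated
        }
        labels = [1, 2, 3, 4] * 10
        assign = label_clusters(self._assignment(labels), self._residuals(means, labels), "Default")
        assert assign.labels[1] == "canonical"
        assert assign.labels[2] == "resilient"
        assert assign.labels[3] == "susceptible"
        assert assign.labels[4] == "dmn-susceptible"

    def test_wrong_k_gets_generic_labels(self):
        means = {1: np.zeros(7), 2: np.full(7, 0.5)}
        labels = [1, 2] * 10
        with pytest.warns(UserWarning, match="expected 4 clusters"):
            assign = label_clusters(self._assignment(labels), self._residuals(means, labels), "Default")
        assert assign.labels[1] == "cluster_1"


class TestEndToEndRecovery:
    def test_planted_groups_recovered(self):
        """Planted susceptibility groups are recovered by the residual-clustering chain."""
        n_ok = 0
        n_rep = 10
        for seed in range(n_rep):
            betas, fcn, labels = plant_mismatch_sample(211, CohortConfig(seed=seed), rng=seed)
            resid, sds = network_residuals(betas, fcn)
            profiles = mismatch_profiles(resid, sds)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                k, _ = choose_k(profiles)
                assign = label_clusters(ward_cluster(profiles, 4), resid, "Default")
            pred = [assign.label_of(i) for i in range(len(labels))]
            ari = adjusted_rand_score(labels.values, pred)
            if k == 4 and ari >= 0.9:
                n_ok += 1
        assert n_ok >= 9
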
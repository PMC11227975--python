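"""Spreading beta, FC-to-epicentre summaries, association and mediation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tauspread import (
    EpicentreSet,
    FCMatrix,
    association_model,
    fc_to_epicentres,
    group_spreading_beta,
    mediate,
    plant_mediation_sample,
    regional_mean,
    spreading_beta,
)
from tauspread.errors import InputError


class TestSpreadingBeta:
    def test_perfect_negative_line(self):
        dist = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        rates = pd.Series([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        res = spreading_beta(rates, dist)
        assert res.beta == pytest.approx(-1.0, abs=1e-12)

    def test_equals_pearson_correlation(self, rng):
        dist = pd.Series(rng.uniform(1, 10, 60))
        rates = pd.Series(rng.normal(0.05, 0.02, 60))
        res = spreading_beta(rates, dist)
        r = stats.pearsonr(rates, dist).statistic
        assert res.beta == pytest.approx(r, abs=1e-12)
        assert res.n_regions_used == 60

    def test_affine_invariance(self, rng):
        dist = pd.Series(rng.uniform(1, 10, 50))
        rates = pd.Series(rng.normal(0.05, 0.02, 50))
        b0 = spreading_beta(rates, dist).beta
        b1 = spreading_beta(rates * 3.2 + 5.0, dist * 0.1 - 2.0).beta
        assert b1 == pytest.approx(b0, abs=1e-12)

    def test_missing_distances_dropped_and_counted(self, rng):
        dist = pd.Series(rng.uniform(1, 10, 40))
        dist.iloc[:5] = np.nan
        rates = pd.Series(rng.normal(0.05, 0.02, 40))
        res = spreading_beta(rates, dist)
        assert res.n_regions_used == 35
        assert res.n_dropped == 5

    def test_zero_variance_errors(self):
        with pytest.raises(InputError):
            spreading_beta(pd.Series(np.ones(20)), pd.Series(np.arange(20.0)))

    def test_monte_carlo_recovery_of_planted_correlation(self):
        rng = np.random.default_rng(7)
        rho, n = -0.3, 190
        betas = []
        for _ in range(500):
            z_d = rng.standard_normal(n)
            rate = rho * z_d + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            betas.append(spreading_beta(pd.Series(rate), pd.Series(z_d)).beta)
        assert -0.35 < np.mean(betas) < -0.25

    def test_euclidean_covariate_changes_dof_not_alignment(self, rng):
        dist = pd.Series(rng.uniform(1, 10, 60))
        rates = pd.Series(-0.02 * dist + rng.normal(0, 0.01, 60))
        euclid = pd.Series(rng.uniform(10, 90, 60))
        res = spreading_beta(rates, dist, euclid=euclid)
        assert res.beta_euclid_adjusted is not None
        assert res.beta == pytest.approx(spreading_beta(rates, dist).beta, abs=0.1)


class TestGroupBeta:
    def test_group_equals_subject_level_when_identical(self, rng):
        dist = rng.uniform(1, 10, 50)
        rate = -0.05 * dist + rng.normal(0, 0.05, 50)
        rates = pd.DataFrame([rate] * 8, index=[f"S{i}" for i in range(8)])
        dists = pd.DataFrame([dist] * 8, index=[f"S{i}" for i in range(8)])
        subject = spreading_beta(pd.Series(rate), pd.Series(dist)).beta
        assert group_spreading_beta(rates, dists, mode="averaged").beta == pytest.approx(subject, abs=1e-10)
        assert group_spreading_beta(rates, dists, mode="pooled").beta == pytest.approx(subject, abs=1e-10)


def _network_labels(n, nets):
    reps = int(np.ceil(n / len(nets)))
    return pd.Series((nets * reps)[:n], index=range(1, n + 1), name="network")


class TestFCtoEpicentres:
    def test_constant_matrix(self):
        n = 12
        z = np.full((n, n), 0.3)
        np.fill_diagonal(z, 0.0)
        fc = FCMatrix(values=z, region_ids=list(range(1, n + 1)))
        epi = EpicentreSet("S1", [1, 2], np.zeros(2))
        res = fc_to_epicentres(fc, epi, _network_labels(n, ["A", "B"]))
        assert res.global_fc == pytest.approx(0.3)
        assert np.allclose(res.per_network.dropna(), 0.3)
        assert res.global_fc == pytest.approx(res.per_region.mean())

    def test_hand_computed_values(self):
        # 4 regions, epicentres {1, 2}; z values set by hand
        z = np.zeros((4, 4))
        z[2, 0], z[2, 1] = 0.4, 0.6  # region 3 -> mean 0.5
        z[3, 0], z[3, 1] = 0.1, 0.3  # region 4 -> mean 0.2
        z = z + z.T
        fc = FCMatrix(values=z, region_ids=[1, 2, 3, 4])
        epi = EpicentreSet("S1", [1, 2], np.zeros(2))
        res = fc_to_epicentres(fc, epi, _network_labels(4, ["A"]))
        assert res.per_region[3] == pytest.approx(0.5)
        assert res.per_region[4] == pytest.approx(0.2)
        assert res.global_fc == pytest.approx(0.35)

    def test_190_per_region_entries(self, rng):
        z = rng.normal(0.2, 0.1, (200, 200))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        fc = FCMatrix(values=z, region_ids=list(range(1, 201)))
        epi = EpicentreSet("S1", list(range(1, 11)), np.zeros(10))
        res = fc_to_epicentres(fc, epi, _network_labels(200, list("ABCDEFG")))
        assert len(res.per_region) == 190

    def test_missing_epicentre_id(self, rng):
        fc = FCMatrix(values=np.zeros((4, 4)), region_ids=[1, 2, 3, 4])
        with pytest.raises(InputError, match="missing"):
            fc_to_epicentres(fc, EpicentreSet("S", [9], np.zeros(1)), _network_labels(4, ["A"]))


class TestRegionalMean:
    def test_trivial_cases(self):
        values = pd.Series({1: 1.0, 2: 1.2, 3: 2.0})
        assert regional_mean(values, [3]) == 2.0
        assert regional_mean(values, [1, 2]) == pytest.approx(1.1)

    def test_weighted_decomposition(self, rng):
        values = pd.Series(rng.uniform(0, 2, 30), index=range(30))
        inside = list(range(10))
        outside = list(range(10, 30))
        recombined = (10 * regional_mean(values, inside) + 20 * regional_mean(values, outside)) / 30
        assert recombined == pytest.approx(values.mean())

    def test_errors(self):
        values = pd.Series({1: 1.0})
        with pytest.raises(InputError, match="empty"):
            regional_mean(values, [])
        with pytest.raises(InputError, match="not in map"):
            regional_mean(values, [5])


class TestAssociationModel:
    def test_reduces_to_pearson_without_covariates(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(80), "x": rng.standard_normal(80)})
        res = association_model(df, "y", "x")
        assert res.coef == pytest.approx(stats.pearsonr(df.y, df.x).statistic, abs=1e-10)

    def test_recovers_planted_coefficient(self, rng):
        n = 500
        x = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        y = 0.4 * x + 0.3 * cov[:, 0] - 0.2 * cov[:, 1] + rng.standard_normal(n) * 0.8
        df = pd.DataFrame({"y": y, "x": x, "age": cov[:, 0], "education": cov[:, 1]})
        res = association_model(df, "y", "x", covariates=["age", "education"])
        assert abs(res.coef - 0.4 / df.y.std(ddof=1)) < 0.1

    def test_duplicated_covariate_is_collinear(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(50), "x": rng.standard_normal(50)})
        df["a"] = rng.standard_normal(50)
        df["b"] = df["a"]
        with pytest.raises(InputError, match="collinear"):
            association_model(df, "y", "x", covariates=["a", "b"])

    def test_binary_covariates_not_standardized(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "x": rng.standard_normal(n),
                "sex": rng.integers(0, 2, n),
            }
        )
        res = association_model(df, "y", "x", covariates=["sex"])
        assert np.isfinite(res.p)


class TestMediate:
    def test_noise_free_closed_form(self):
        # m carries a vanishing perturbation so that x and m stay
        # numerically distinguishable; y is an exact linear combination
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        m = 0.4 * x + 1e-6 * rng.standard_normal(200)
        y = 0.5 * x + 0.5 * m
        res = mediate(x, m, y, n_boot=200, seed=0)
        assert res.acme == pytest.approx(0.20, abs=1e-6)
        assert res.total_effect == pytest.approx(0.70, abs=1e-6)
        assert res.proportion_mediated == pytest.approx(0.2 / 0.7, abs=1e-6)

    def test_acme_plus_ade_equals_total(self):
        x, m, y = plant_mediation_sample(300, rng=5)
        res = mediate(x, m, y, n_boot=100, seed=0)
        assert res.acme + res.ade == pytest.approx(res.total_effect, abs=1e-8)

    def test_null_mediation_ci_covers_zero(self, rng):
        x = rng.standard_normal(200)
        m = rng.standard_normal(200)  # independent of x
        y = 0.5 * x + 0.3 * m + 0.5 * rng.standard_normal(200)
        res = mediate(x, m, y, n_boot=500, seed=1)
        assert res.ci_acme[0] < 0 < res.ci_acme[1]
        assert abs(res.acme) < 0.1

    def test_seed_reproducibility(self):
        x, m, y = plant_mediation_sample(150, rng=2)
        a = mediate(x, m, y, n_boot=300, seed=42)
        b = mediate(x, m, y, n_boot=300, seed=42)
        assert a.ci_acme == b.ci_acme
        assert a.ci_proportion == b.ci_proportion

    def test_covariates_controlled(self, rng):
        n = 300
        age = rng.standard_normal(n)
        x = 0.5 * age + rng.standard_normal(n)
        m = 0.4 * x + 0.3 * age + 0.4 * rng.standard_normal(n)
        y = 0.15 * x + 0.125 * m + 0.2 * age + 0.3 * rng.standard_normal(n)
        res = mediate(x, m, y, covariates=age, n_boot=300, seed=3)
        assert res.acme + res.ade == pytest.approx(res.total_effect, abs=1e-8)

    def test_too_few_cases(self, rng):
        with pytest.raises(InputError, match=">=30"):
            mediate(rng.standard_normal(10), rng.standard_normal(10), rng.standard_normal(10))

    def test_degenerate_variance(self, rng):
        x = rng.standard_normal(50)
        with pytest.raises(InputError, match="degenerate variance"):
            mediate(x, np.ones(50), x)

    def test_small_bootstrap_warns(self, rng):
        x, m, y = plant_mediation_sample(100, rng=rng)
        with pytest.warns(UserWarning, match="n_boot"):
            mediate(x, m, y, n_boot=50, seed=0)
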
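import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis
from scipy.stats import binom

from trialmon import (AnomalySpec, MonitoringConfig, SynthConfig,
                      build_centre_features, detect, equivalent_radius,
                      fit_common_model, flag_centres, generate_trial,
                      inject_anomalies, mahalanobis_distance,
                      observed_distances, resample_centre_distances)
from trialmon.anomaly import CommonModel, DistanceDistribution
from trialmon.errors import InsufficientCentresError
from trialmon.synthgen import continuous_panel
from trialmon.trial_model import VariableDef

from conftest import build_dataset


def manual_model(mu, sigma):
    p = len(mu)
    return CommonModel(
        feature_names=[f"f{i}" for i in range(p)],
        location=np.asarray(mu, float), scale=np.ones(p),
        covariance=np.asarray(sigma, float), shrinkage_used=0.0,
        dropped_features=[], feature_index=np.arange(p),
        _chol=np.linalg.cholesky(sigma))


class TestDistance:
    def test_agrees_with_brute_force_solve(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(300):
            p = int(rng.integers(1, 9))
            A = rng.normal(size=(p, p))
            sigma = A @ A.T + 0.5 * np.eye(p)
            mu, x = rng.normal(size=p), rng.normal(size=p)
            model = manual_model(mu, sigma)
            d = mahalanobis_distance(x, model)
            ref = np.sqrt((x - mu) @ np.linalg.solve(sigma, x - mu))
            worst = max(worst, abs(d - ref))
            assert d == pytest.approx(
                scipy_mahalanobis(x, mu, np.linalg.inv(sigma)), abs=1e-8)
        assert worst < 1e-10

    def test_distance_at_mean_is_zero(self):
        model = manual_model([1.0, 2.0], np.eye(2))
        assert mahalanobis_distance([1.0, 2.0], model) == 0.0

    def test_one_feature_reduces_to_z_score(self):
        # x = mu + 2*scale with unit standardised covariance gives d = 2
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        from trialmon.anomaly import CentreFeatureMatrix
        feats = CentreFeatureMatrix(
            ["A", "B", "C", "D"], ["f"], X,
            {c: 10 for c in "ABCD"}, [], [],
            {c: X[i:i + 1] for i, c in enumerate("ABCD")})
        model = fit_common_model(
            feats, MonitoringConfig(covariance_shrinkage=0.0))
        x = model.location + 2 * model.scale
        assert mahalanobis_distance(x, model) == pytest.approx(2.0)

    def test_full_shrinkage_is_z_score_quadrature(self):
        rng = np.random.default_rng(3)
        ds, _ = generate_trial(SynthConfig(
            n_centres=8, participants_per_centre=10,
            variable_panel=continuous_panel(3), rng_seed=3))
        cfg = MonitoringConfig(covariance_shrinkage=1.0)
        feats = build_centre_features(ds, cfg)
        model = fit_common_model(feats, cfg)
        d = observed_distances(feats, model)
        Z = (feats.values[:, model.feature_index] - model.location
             ) / model.scale
        np.testing.assert_allclose(d, np.sqrt((Z ** 2).sum(axis=1)),
                                   atol=1e-10)

    def test_dimension_mismatch_is_an_error(self):
        model = manual_model([0.0, 0.0], np.eye(2))
        from trialmon.errors import ConfigError
        with pytest.raises(ConfigError):
            mahalanobis_distance([1.0], model)


class TestExclusionRules:
    def test_small_centre_excluded(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=4, participants_per_centre=[4, 10, 10, 10],
            variable_panel=continuous_panel(3), rng_seed=0))
        feats = build_centre_features(ds)
        assert ("C01", "small_centre") in feats.excluded_centres
        assert "C01" not in feats.centre_ids

    def test_sparse_feature_dropped(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=3, participants_per_centre=10,
            variable_panel=continuous_panel(3), missingness_rate=0.0,
            rng_seed=1))
        v = ds.values
        rows = v.index[(v["variable_name"] == "score_02")
                       & v["participant_id"].str.startswith("C02")][:6]
        ds.values = v.drop(rows).reset_index(drop=True)  # 4 entries remain
        feats = build_centre_features(ds)
        assert ("score_02", "sparse_feature") in feats.excluded_features
        assert "score_02" not in feats.feature_names

    def test_fewer_than_three_centres_is_an_error(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=3, participants_per_centre=[4, 4, 10],
            variable_panel=continuous_panel(3), rng_seed=2))
        with pytest.raises(InsufficientCentresError):
            build_centre_features(ds)

    def test_zero_variance_feature_dropped_at_fit(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=4, participants_per_centre=8,
            variable_panel=continuous_panel(2), missingness_rate=0.0,
            rng_seed=3))
        const = pd.DataFrame({
            "participant_id": ds.participants["participant_id"],
            "variable_name": "flatline", "value": 1.0})
        ds.values = pd.concat([ds.values, const], ignore_index=True)
        ds.dictionary.append(VariableDef("flatline", "continuous",
                                         monitored=True))
        feats = build_centre_features(ds)
        model = fit_common_model(feats)
        assert ("flatline", "zero_variance") in model.dropped_features
        assert "flatline" not in model.feature_names

    def test_binary_feature_cell_is_the_centre_proportion(self):
        values = []
        for c, k in (("C01", 7), ("C02", 5), ("C03", 3)):
            for i in range(10):
                values.append((f"{c}-P{i}", "ev", "yes" if i < k else "no"))
        parts = [{"pid": pid, "centre": pid[:3]} for pid, _, _ in values]
        ds = build_dataset(parts, values=values, dictionary=[
            VariableDef("ev", "binary", levels=("no", "yes"),
                        monitored=True)])
        feats = build_centre_features(ds)
        assert feats.values[feats.centre_ids.index("C01"), 0] == 0.7


class TestResampling:
    def test_degenerate_centre_resamples_to_observed(self):
        values = []
        for i in range(6):
            values.append((f"C01-P{i}", "x", 5.0))
        for c, base in (("C02", 4.0), ("C03", 6.0)):
            for i in range(6):
                values.append((f"{c}-P{i}", "x", base + 0.3 * i))
        parts = [{"pid": pid, "centre": pid[:3]} for pid, _, _ in values]
        ds = build_dataset(parts, values=values, dictionary=[
            VariableDef("x", "continuous", monitored=True)])
        cfg = MonitoringConfig(covariance_shrinkage=0.0, n_resamples=500)
        feats = build_centre_features(ds, cfg)
        model = fit_common_model(feats, cfg)
        dists = resample_centre_distances(feats, model, cfg, seed=0)
        c01 = next(d for d in dists if d.centre_id == "C01")
        assert np.allclose(c01.distances, c01.observed)

    def test_same_seed_reproduces_distributions(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=4, participants_per_centre=8,
            variable_panel=continuous_panel(2), rng_seed=5))
        cfg = MonitoringConfig(n_resamples=400)
        feats = build_centre_features(ds, cfg)
        model = fit_common_model(feats, cfg)
        a = resample_centre_distances(feats, model, cfg, seed=9)
        b = resample_centre_distances(feats, model, cfg, seed=9)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.distances, db.distances)

    def test_bootstrap_proportion_is_binomial(self):
        # one binary feature: the resampled centre proportion must follow
        # Binomial(n, p_hat)/n exactly; compare atom frequencies at B=10000
        values = []
        for c, k in (("C01", 10), ("C02", 8), ("C03", 12), ("C04", 9)):
            for i in range(20):
                values.append((f"{c}-P{i:02d}", "ev",
                               "yes" if i < k else "no"))
        parts = [{"pid": pid, "centre": pid[:3]} for pid, _, _ in values]
        ds = build_dataset(parts, values=values, dictionary=[
            VariableDef("ev", "binary", levels=("no", "yes"),
                        monitored=True)])
        cfg = MonitoringConfig(covariance_shrinkage=0.0, n_resamples=10_000)
        feats = build_centre_features(ds, cfg)
        model = fit_common_model(feats, cfg)
        dists = resample_centre_distances(feats, model, cfg, seed=1)
        c01 = next(d for d in dists if d.centre_id == "C01")
        n = 20
        atoms = np.array([mahalanobis_distance(np.array([k / n]), model)
                          for k in range(n + 1)])
        nearest = np.argmin(
            np.abs(c01.distances[:, None] - atoms[None, :]), axis=1)
        freq = np.bincount(nearest, minlength=n + 1) / len(c01.distances)
        pmf = binom.pmf(np.arange(n + 1), n, 0.5)
        assert 0.5 * np.abs(freq - pmf).sum() < 0.025


class TestFlagsAndPipeline:
    def test_equivalent_radius_matches_threshold_in_1d(self):
        assert equivalent_radius(2.0, 1) == pytest.approx(2.0)
        assert equivalent_radius(2.0, 6) > 2.0

    def test_tier_rules(self):
        def dist(values):
            return DistanceDistribution("C", float(np.median(values)),
                                        np.asarray(values, float),
                                        len(values), 0)
        cfg = MonitoringConfig()
        below = dist(np.full(1000, 1.5))
        assert flag_centres([below], 1, cfg)[0].tier == "none"
        spread = dist(np.r_[np.full(100, 1.8), np.full(900, 2.5)])
        assert flag_centres([spread], 1, cfg)[0].tier == "suspected"
        tight = dist(np.full(1000, 2.4))
        assert flag_centres([tight], 1, cfg)[0].tier == "confirmed"

    def test_planted_shift_confirmed_in_one_replicate(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=20, participants_per_centre=20,
            variable_panel=continuous_panel(6), rng_seed=8))
        ds2, _ = inject_anomalies(ds, [AnomalySpec(
            "misunderstanding", "C07", "score_02", magnitude=5.0,
            affected_fraction=1.0)], seed=8)
        res = detect(ds2, MonitoringConfig(n_resamples=2000, rng_seed=8))
        tiers = {f.centre_id: f.tier for f in res.flags}
        assert tiers["C07"] == "confirmed"
        assert all(t != "confirmed" for c, t in tiers.items() if c != "C07")

    def test_results_blind_to_allocation_permutation(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=5, participants_per_centre=10,
            variable_panel=continuous_panel(3), rng_seed=9))
        res1 = detect(ds, MonitoringConfig(n_resamples=300, rng_seed=1))
        rng = np.random.default_rng(0)
        permuted = ds._allocation.copy()
        permuted[:] = rng.permutation(permuted.to_numpy())
        from trialmon.trial_model import TrialDataset
        ds2 = TrialDataset(ds.participants.copy(), ds.entries.copy(),
                           ds.values.copy(), list(ds.dictionary),
                           ds.snapshot_date, permuted)
        res2 = detect(ds2, MonitoringConfig(n_resamples=300, rng_seed=1))
        pd.testing.assert_frame_equal(res1.table(), res2.table())

    def test_detect_is_deterministic_under_seed(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=5, participants_per_centre=10,
            variable_panel=continuous_panel(3), rng_seed=10))
        cfg = MonitoringConfig(n_resamples=300, rng_seed=4)
        pd.testing.assert_frame_equal(detect(ds, cfg).table(),
                                      detect(ds, cfg).table())
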
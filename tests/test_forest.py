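"""Random-forest index prediction, Cohen's kappa and the evaluation suite."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from ednaibch import (
    ConfigError,
    RfConfig,
    SiteDetectionTable,
    ValidationError,
    build_presence_features,
    cohen_kappa,
    evaluate_predictions,
    kappa_band,
    predict_scores,
    tune_hyperparameters,
)


def table_from(pooled):
    frame = pd.DataFrame(
        pooled, columns=[f"o{j}" for j in range(pooled.shape[1])],
        index=[f"S{i}" for i in range(pooled.shape[0])],
    )
    return SiteDetectionTable(presence=frame > 0, pooled_reads=frame)


class TestFeatures:
    def test_binary_and_constant_columns_dropped(self):
        pooled = np.array([[57, 0, 5], [12, 0, 7], [0, 0, 3]])
        X = build_presence_features(table_from(pooled))
        assert set(np.unique(X.to_numpy())) <= {0, 1}
        assert list(X.columns) == ["o0"]  # o1 all-absent, o2 all-present

    def test_all_present_matrix_has_no_information(self):
        with pytest.raises(ValidationError, match="no informative"):
            build_presence_features(table_from(np.ones((3, 4), dtype=int)))

    def test_fewer_than_two_sites_rejected(self):
        with pytest.raises(ValidationError):
            build_presence_features(table_from(np.array([[1, 0]])))


def random_features(rng, n=40, p=12):
    X = pd.DataFrame(
        rng.integers(0, 2, size=(n, p)),
        columns=[f"o{j}" for j in range(p)],
        index=[f"S{i}" for i in range(n)],
    )
    return X


class TestTuning:
    def test_singleton_grid_returned_unchanged(self):
        rng = np.random.default_rng(1)
        X = random_features(rng)
        y = rng.normal(10, 2, len(X))
        grid = {"mtry": [4], "min_node_size": [3], "ntrees": [50]}
        cfg = tune_hyperparameters(X, y, grid=grid, seed=5)
        assert (cfg.mtry, cfg.min_node_size, cfg.ntrees) == (4, 3, 50)

    def test_noise_response_rmse_near_response_sd(self):
        rng = np.random.default_rng(2)
        X = random_features(rng, n=60)
        y = rng.normal(0, 1, len(X))
        grid = {"mtry": [4], "min_node_size": [5], "ntrees": [100]}
        cfg = tune_hyperparameters(X, y, grid=grid, seed=5)
        assert cfg.cv_rmse == pytest.approx(np.std(y), rel=0.15)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = random_features(rng)
        y = rng.normal(10, 2, len(X))
        grid = {"mtry": [3, 6], "min_node_size": [3, 5], "ntrees": [50]}
        c1 = tune_hyperparameters(X, y, grid=grid, seed=9)
        c2 = tune_hyperparameters(X, y, grid=grid, seed=9)
        assert (c1.mtry, c1.min_node_size, c1.cv_rmse) == (
            c2.mtry, c2.min_node_size, c2.cv_rmse
        )

    def test_oversized_mtry_cells_skipped(self):
        rng = np.random.default_rng(4)
        X = random_features(rng, p=5)
        y = rng.normal(size=len(X))
        grid = {"mtry": [99], "min_node_size": [3], "ntrees": [10]}
        with pytest.raises(ConfigError, match="no valid cell"):
            tune_hyperparameters(X, y, grid=grid, seed=1)


class TestPrediction:
    def test_constant_response_predicted_exactly(self):
        rng = np.random.default_rng(5)
        X = random_features(rng, n=20)
        y = np.full(20, 7.0)
        cfg = RfConfig(ntrees=50, seed=1)
        preds = predict_scores(X, y, cfg)
        assert (preds == 7.0).all()

    def test_single_informative_feature_recovered(self):
        rng = np.random.default_rng(6)
        n = 40
        f = rng.integers(0, 2, n)
        X = random_features(rng, n=n, p=6)
        X["signal"] = f
        y = 5.0 + 10.0 * f
        cfg = RfConfig(ntrees=300, mtry=5, seed=2)
        preds = predict_scores(X, y, cfg)
        close = np.abs(preds.to_numpy() - y) <= 1.0
        assert close.mean() >= 0.9

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(7)
        X = random_features(rng, n=25)
        y = rng.normal(10, 3, 25)
        cfg = RfConfig(ntrees=50, seed=3)
        p1 = predict_scores(X, y, cfg)
        p2 = predict_scores(X, y, cfg)
        assert p1.equals(p2)

    def test_predictions_within_observed_range(self):
        rng = np.random.default_rng(8)
        X = random_features(rng, n=30)
        y = rng.uniform(5, 17, 30)
        for scheme in ("leave_one_out", "out_of_bag"):
            cfg = RfConfig(ntrees=60, seed=4, prediction_scheme=scheme)
            preds = predict_scores(X, y, cfg).to_numpy()
            assert preds.min() >= y.min() - 1e-9
            assert preds.max() <= y.max() + 1e-9

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigError):
            RfConfig(prediction_scheme="bootstrap", seed=1)


class TestCohenKappa:
    def test_identical_vectors(self):
        assert cohen_kappa(list("AABB"), list("AABB")) == pytest.approx(1.0)

    def test_hand_example_exact(self):
        # p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        k = cohen_kappa(list("AABB"), list("ABBB"))
        assert k == pytest.approx(0.5, abs=1e-12)

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            a = rng.choice(list("WXYZ"), 60)
            b = rng.choice(list("WXYZ"), 60)
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        a = rng.choice(list("ABCD"), 50)
        b = rng.choice(list("ABCD"), 50)
        mapping = {"A": "q", "B": "r", "C": "s", "D": "t"}
        a2 = np.array([mapping[x] for x in a])
        b2 = np.array([mapping[x] for x in b])
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(a2, b2))

    def test_independent_shuffles_mean_near_zero(self):
        rng = np.random.default_rng(12)
        a = rng.choice(list("ABCD"), 200)
        vals = [cohen_kappa(a, rng.permutation(a)) for _ in range(300)]
        assert abs(float(np.mean(vals))) < 0.02

    def test_degenerate_marginals(self):
        with pytest.warns(UserWarning):
            assert cohen_kappa(["A", "A"], ["A", "A"]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            cohen_kappa(["A"], ["A", "B"])


class TestKappaBand:
    @pytest.mark.parametrize("kappa,label", [
        (0.02, "no agreement"),
        (0.5, "fair"),
        (0.6, "good"),
        (0.8, "very good"),
        (0.9, "excellent"),
        (0.995, "excellent"),
        (1.0, "perfect"),
        (-0.3, "no agreement"),
    ])
    def test_band_labels(self, kappa, label):
        assert kappa_band(kappa) == label

    @pytest.mark.parametrize("kappa,label", [
        (0.05, "no agreement"), (0.20, "very poor"), (0.40, "poor"),
        (0.55, "fair"), (0.70, "good"), (0.85, "very good"),
    ])
    def test_boundaries_fall_to_lower_band(self, kappa, label):
        assert kappa_band(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            kappa_band(1.2)


class TestEvaluation:
    def test_perfect_predictions(self):
        obs = np.array([6.0, 10.0, 14.0, 18.0, 11.0])
        ev = evaluate_predictions(obs, obs)
        assert ev.regression.adj_r_squared == pytest.approx(1.0)
        assert ev.kappa == pytest.approx(1.0)
        assert ev.pct_exact == 100.0
        assert ev.kappa_band == "perfect"

    def test_one_category_shift(self):
        obs = np.array([6.0, 7.0, 10.0, 11.0, 6.0])
        pred = obs + 4.0  # exactly one category upward everywhere
        ev = evaluate_predictions(obs, pred)
        assert ev.pct_exact == 0.0
        assert ev.pct_within_one == 100.0
        assert set(ev.deviation_histogram) == {1}

    def test_histogram_sums_to_hundred(self):
        rng = np.random.default_rng(13)
        obs = rng.uniform(5, 18, 40)
        pred = np.clip(obs + rng.normal(0, 3, 40), 0, 20)
        ev = evaluate_predictions(obs, pred)
        assert sum(ev.deviation_histogram.values()) == pytest.approx(100.0)

    def test_rounding_is_half_up(self):
        # 12.5 rounds to 13 ("good"), not 12 ("moderate")
        obs = np.array([13.0, 13.0, 13.0])
        pred = np.array([12.5, 12.5, 12.5])
        ev = evaluate_predictions(obs, pred)
        assert ev.pct_exact == 100.0

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_predictions([1.0, 2.0], [1.0, 2.0])
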
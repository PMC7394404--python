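import numpy as np
import pytest

from conftest import make_dataset
from misvote.ensemble import (
    ModelFileError,
    SoftVotingModel,
    classify,
    feature_weight_report,
    fit_soft_voting,
    load_model,
    predict_score,
    rfe_rank,
    save_model,
    select_top_k,
)
from misvote.evaluate import auc_score


def _informative_noise_data(seed, n=200, n_inf=10, n_noise=5, effect=2.5):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    X_inf = rng.normal(size=(n, n_inf)) + effect * y[:, None]
    X_noise = rng.normal(size=(n, n_noise))
    names = [f"inf{j}" for j in range(n_inf)] + [f"noise{j}" for j in range(n_noise)]
    return make_dataset(np.hstack([X_inf, X_noise]), y, names), names


class TestRfeRank:
    def test_noise_features_eliminated_early(self):
        """Pure-noise features should fall in the earliest eliminations on
        clearly separable data, for a majority of seeds."""
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            ds, _ = _informative_noise_data(seed)
            trace = rfe_rank(ds, "tree", step=1, cv_folds=2, seed=seed)
            first7 = set(trace.elimination_order[:7])
            if sum(1 for f in first7 if f.startswith("noise")) >= 4:
                wins += 1
        assert wins > n_seeds / 2

    def test_single_round_has_two_curve_points(self):
        ds, _ = _informative_noise_data(0, n=80, n_inf=4, n_noise=2)
        trace = rfe_rank(ds, "tree", step=5, cv_folds=2, seed=0)
        assert len(trace.performance_curve) == 2
        assert trace.performance_curve[0][0] == 6
        assert trace.performance_curve[-1][0] == 1

    def test_duplicate_column_eliminated_in_first_half(self):
        rng = np.random.default_rng(3)
        n = 200
        y = np.repeat([1, 0], n // 2)
        base = rng.normal(size=(n, 5)) + 2.0 * y[:, None]
        noise = rng.normal(size=(n, 2))
        X = np.hstack([base[:, :1], base[:, :1], base[:, 1:], noise])
        names = ["dupA", "dupB", "i1", "i2", "i3", "i4", "n1", "n2"]
        trace = rfe_rank(make_dataset(X, y, names), "linear", step=1, cv_folds=2, seed=3)
        positions = {f: i for i, f in enumerate(trace.elimination_order)}
        assert min(positions["dupA"], positions["dupB"]) <= 3

    def test_elimination_order_complete_and_unique(self):
        ds, names = _informative_noise_data(1, n=100, n_inf=4, n_noise=3)
        trace = rfe_rank(ds, "linear", step=2, cv_folds=2, seed=1)
        assert sorted(trace.elimination_order) == sorted(names)

    def test_single_class_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(20, 3)), np.ones(20))
        with pytest.raises(ValueError, match="both classes"):
            rfe_rank(ds, "tree", cv_folds=2)


class TestSelectTopK:
    def _trace(self):
        ds, _ = _informative_noise_data(2, n=80, n_inf=4, n_noise=2)
        return rfe_rank(ds, "tree", step=1, cv_folds=2, seed=2)

    def test_k_total_returns_all(self):
        trace = self._trace()
        assert sorted(select_top_k(trace, 6)) == sorted(trace.elimination_order)

    def test_k_one_is_last_survivor(self):
        trace = self._trace()
        assert select_top_k(trace, 1) == [trace.elimination_order[-1]]

    def test_selected_disjoint_from_earliest_eliminated(self):
        trace = self._trace()
        top3 = set(select_top_k(trace, 3))
        assert not (top3 & set(trace.elimination_order[:3]))

    @pytest.mark.parametrize("k", [0, 7])
    def test_out_of_range_rejected(self, k):
        with pytest.raises(ValueError, match="k must be"):
            select_top_k(self._trace(), k)


class _StubLearner:
    """Constant-probability learner for exact soft-vote arithmetic."""

    def __init__(self, p):
        self.p = float(p)

    def predict_proba(self, X):
        n = len(X)
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])


def _stub_model(p_tree, p_linear, weights, separable_ds):
    names = separable_ds.matrix.manifest.names
    return SoftVotingModel(
        tree=_StubLearner(p_tree),
        linear=_StubLearner(p_linear),
        scaler=None,
        features_tree=list(names),
        features_linear=list(names),
        weights=weights,
    )


class TestPredictScore:
    def test_equal_weights_arithmetic_mean(self, separable_ds):
        model = _stub_model(0.8, 0.6, (0.5, 0.5), separable_ds)
        s = predict_score(model, separable_ds.matrix)
        np.testing.assert_allclose(s, 0.7)

    def test_weighted_average(self, separable_ds):
        model = _stub_model(0.8, 0.4, (0.75, 0.25), separable_ds)
        np.testing.assert_allclose(predict_score(model, separable_ds.matrix), 0.7)

    @pytest.mark.parametrize("weights,expect", [((1.0, 0.0), 0.8), ((0.0, 1.0), 0.3)])
    def test_degenerate_weights_recover_single_learner(
        self, weights, expect, separable_ds
    ):
        model = _stub_model(0.8, 0.3, weights, separable_ds)
        np.testing.assert_allclose(predict_score(model, separable_ds.matrix), expect)

    def test_score_within_convex_hull(self, trained_model, separable_ds):
        s = predict_score(trained_model, separable_ds.matrix)
        pt = trained_model.tree.predict_proba(
            separable_ds.matrix.column_values(trained_model.features_tree)
        )[:, 1]
        pl = trained_model.linear.predict_proba(
            trained_model.scaler.transform(
                separable_ds.matrix.column_values(trained_model.features_linear)
            )
        )[:, 1]
        assert np.all(s >= np.minimum(pt, pl) - 1e-12)
        assert np.all(s <= np.maximum(pt, pl) + 1e-12)

    def test_row_order_invariance(self, trained_model, separable_ds):
        s = predict_score(trained_model, separable_ds.matrix)
        perm = np.random.default_rng(0).permutation(len(separable_ds))
        s_perm = predict_score(trained_model, separable_ds.matrix.take(perm))
        np.testing.assert_allclose(s_perm, s[perm])

    def test_missing_feature_named(self, trained_model, separable_ds):
        reduced = separable_ds.matrix.manifest.subset(
            separable_ds.matrix.manifest.names[:-1]
        )
        from misvote.features import FeatureMatrix

        m = separable_ds.matrix
        sub = FeatureMatrix(
            m.variants, reduced, m.values[:, :-1], m.coverage[:, :-1]
        )
        with pytest.raises(KeyError, match=m.manifest.names[-1]):
            predict_score(trained_model, sub)


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected", [(0.51, 1), (0.5, 0), (0.0, 0), (1.0, 1), (0.499, 0)]
    )
    def test_strict_threshold(self, score, expected):
        assert classify(np.array([score]))[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            classify(np.array([1.2]))


class TestFitSoftVoting:
    def test_separable_data_high_heldout_auc(self, trained_model, small_manifest,
                                             small_aaindex):
        from misvote.synthdata import generate_labeled_features

        test = generate_labeled_features(
            80, small_manifest, effect_size=3.0, noise_fraction=0.0,
            seed=99, aaindex_set=small_aaindex,
        )
        auc = auc_score(test.labels, predict_score(trained_model, test.matrix))
        assert auc > 0.95

    def test_reproducible_under_seed(self, separable_ds):
        m1 = fit_soft_voting(separable_ds, n_iter=2, cv_folds=2, seed=42)
        m2 = fit_soft_voting(separable_ds, n_iter=2, cv_folds=2, seed=42)
        assert m1.train_metadata["best_params"] == m2.train_metadata["best_params"]
        np.testing.assert_array_equal(
            predict_score(m1, separable_ds.matrix),
            predict_score(m2, separable_ds.matrix),
        )

    def test_minimal_search_is_valid(self, separable_ds):
        model = fit_soft_voting(separable_ds, n_iter=1, cv_folds=2, seed=0)
        s = predict_score(model, separable_ds.matrix)
        assert np.all((s >= 0) & (s <= 1))

    def test_nonfinite_values_rejected(self):
        ds = make_dataset(np.ones((20, 3)), np.repeat([0, 1], 10))
        # an uncovered NaN cell: legal matrix, but unusable for training
        ds.matrix.values[0, 0] = np.nan
        ds.matrix.coverage[0, 0] = False
        with pytest.raises(ValueError, match="non-finite"):
            fit_soft_voting(ds, n_iter=1, cv_folds=2, seed=0)

    def test_imbalance_warning_recorded(self, rng):
        y = np.array([1] * 4 + [0] * 60)
        X = rng.normal(size=(64, 3)) + y[:, None]
        model = fit_soft_voting(make_dataset(X, y), n_iter=1, cv_folds=2, seed=0)
        assert any("imbalance" in w for w in model.train_metadata["warnings"])

    def test_unequal_feature_counts_rejected(self, separable_ds):
        names = separable_ds.matrix.manifest.names
        with pytest.raises(ValueError, match="same number"):
            fit_soft_voting(
                separable_ds, names[:3], names[:2], n_iter=1, cv_folds=2
            )


class TestFeatureWeightReport:
    def test_weights_sum_to_100(self, trained_model):
        report = feature_weight_report(trained_model)
        for learner in ("tree", "linear"):
            assert sum(report[learner].values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_informative_feature_dominates_tree(self):
        wins = 0
        n_seeds = 3
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = np.repeat([1, 0], 60)
            X = rng.normal(size=(120, 5))
            X[:, 2] += 3.0 * y
            model = fit_soft_voting(
                make_dataset(X, y), n_iter=1, cv_folds=2, seed=seed
            )
            report = feature_weight_report(model)["tree"]
            if max(report, key=report.get) == "f2":
                wins += 1
        assert wins > n_seeds / 2


class TestPersistence:
    def test_round_trip_scores_identical(self, trained_model, separable_ds, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(trained_model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            predict_score(loaded, separable_ds.matrix),
            predict_score(trained_model, separable_ds.matrix),
        )

    def test_metadata_passthrough(self, trained_model, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(trained_model, path)
        assert load_model(path).train_metadata == trained_model.train_metadata

    def test_truncated_file_rejected(self, trained_model, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(trained_model, path)
        path.write_bytes(path.read_bytes()[:50])
        with pytest.raises(ModelFileError):
            load_model(path)

    def test_non_model_file_rejected(self, tmp_path):
        path = tmp_path / "other.joblib"
        import joblib

        joblib.dump({"unrelated": 1}, path)
        with pytest.raises(ModelFileError, match="not a model file"):
            load_model(path)
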
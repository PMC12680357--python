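import numpy as np
import pandas as pd
import pytest

from cranioplan.shape_model import StatisticalShapeModel
from cranioplan.surrogate import (
    MODEL_KINDS,
    SEARCH_SPACES,
    SurrogateRegressor,
    evaluate_model,
    make_model,
    screen_models,
    search_hyperparams,
    split_and_scale,
    train_model,
)


def _linear_data(n=200, d_in=5, d_out=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d_in))
    W = rng.normal(size=(d_in, d_out))
    Y = X @ W + noise * rng.normal(size=(n, d_out))
    return X, Y


def _fake_dataset(n_rows=2356, k_in=11, k_out=11, seed=0):
    rng = np.random.default_rng(seed)
    cols = {}
    cols["age_days"] = rng.integers(90, 300, n_rows).astype(float)
    cols["A"] = rng.uniform(0.18, 0.30, n_rows)
    cols["AP"] = rng.uniform(0.47, 0.63, n_rows)
    cols["LAT"] = rng.uniform(0.10, 0.25, n_rows)
    cols["ant_k"] = rng.choice([0.5, 1.0, 1.5], n_rows)
    cols["ant_L0"] = np.full(n_rows, 60.0)
    cols["post_k"] = rng.choice([0.5, 1.0, 1.5], n_rows)
    cols["post_L0"] = np.full(n_rows, 60.0)
    for i in range(k_in):
        cols[f"b_in_{i + 1}"] = rng.normal(size=n_rows)
    for i in range(k_out):
        cols[f"b_out_{i + 1}"] = rng.normal(size=n_rows)
    return pd.DataFrame(cols)


class TestAssembleDataset:
    def test_layout_on_corpus(self, trained_corpus):
        corpus, _, _, _ = trained_corpus
        total = sum(len(p) for p in corpus.plans.values())
        k_in, k_out = corpus.ssm_in.n_modes_, corpus.ssm_out.n_modes_
        assert corpus.dataset.shape == (total, 8 + k_in + k_out)
        assert not corpus.dataset.isna().any().any()

    def test_eleven_plus_eleven_modes_give_thirty_columns(self, trained_corpus):
        from cranioplan.surrogate import assemble_dataset

        corpus, _, _, _ = trained_corpus
        rng = np.random.default_rng(0)
        n_feat = corpus.dataset.filter(like="b_in").shape[1]
        # shape models with eleven retained modes each reproduce the
        # published 8 + 11 + 11 = 30-column layout
        ssm11_in = StatisticalShapeModel(variance_threshold=1.0).fit(
            rng.normal(size=(20, 45)))
        ssm11_in.n_modes_ = 11
        ssm11_out = StatisticalShapeModel(variance_threshold=1.0).fit(
            rng.normal(size=(20, 45)))
        ssm11_out.n_modes_ = 11
        plans = {0: corpus.plans[0]}
        shapes_in = {0: rng.normal(size=45)}
        shapes_out = {(0, cid): rng.normal(size=45)
                      for cid in range(len(corpus.plans[0]))}
        df = assemble_dataset(ssm11_in, ssm11_out, plans, corpus.patients,
                              shapes_in, shapes_out)
        assert df.shape[1] == 30

    def test_missing_simulation_rejected(self, trained_corpus):
        from cranioplan.surrogate import assemble_dataset

        corpus, _, _, _ = trained_corpus
        broken = dict(corpus.sim_shapes)
        broken.pop((0, 0))
        with pytest.raises(ValueError, match="missing"):
            assemble_dataset(corpus.ssm_in, corpus.ssm_out, corpus.plans,
                             corpus.patients, corpus.preop_shapes, broken)


class TestSplitAndScale:
    def test_published_split_size(self):
        split = split_and_scale(_fake_dataset(2356), test_fraction=0.33, seed=0)
        assert len(split.X_test) == 778
        assert len(split.X_train) == 2356 - 778

    def test_train_columns_standardised(self):
        split = split_and_scale(_fake_dataset(500), seed=1)
        nondeg = [i for i, n in enumerate(split.feature_names)
                  if n not in split.degenerate_columns]
        assert np.abs(split.X_train[:, nondeg].mean(axis=0)).max() < 1e-10
        assert np.abs(split.X_train[:, nondeg].std(axis=0) - 1).max() < 1e-10
        assert np.abs(split.Y_train.mean(axis=0)).max() < 1e-10

    def test_degenerate_columns_flagged_and_centred(self):
        split = split_and_scale(_fake_dataset(300), seed=2)
        assert "ant_L0" in split.degenerate_columns
        i = split.feature_names.index("ant_L0")
        assert np.abs(split.X_train[:, i]).max() < 1e-10   # centred, not blown up

    def test_no_leakage_from_test_rows(self):
        split = split_and_scale(_fake_dataset(800), seed=3)
        # scaler fitted on train only: scaled test columns are not exactly
        # standard in general
        assert np.abs(split.X_test.mean(axis=0)).max() > 1e-6

    def test_same_seed_same_split(self):
        ds = _fake_dataset(400)
        s1 = split_and_scale(ds, seed=5)
        s2 = split_and_scale(ds, seed=5)
        np.testing.assert_array_equal(s1.test_index, s2.test_index)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_and_scale(_fake_dataset(100), test_fraction=1.5)


class TestTrainModel:
    def test_linear_regression_exact_on_linear_data(self):
        X, Y = _linear_data()
        model = train_model("lr", X, Y)
        rep = evaluate_model(model, X, Y)
        assert rep.r2 == pytest.approx(1.0, abs=1e-10)

    def test_svr_with_published_optimum_trains(self):
        X, Y = _linear_data(n=100)
        model = train_model("svm", X, Y,
                            {"kernel": "rbf", "C": 1.85, "epsilon": 0.0})
        assert model.predict(X).shape == Y.shape

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_all_kinds_fit_and_are_deterministic(self, kind):
        X, Y = _linear_data(n=80, noise=0.1)
        p1 = train_model(kind, X, Y, seed=3).predict(X)
        p2 = train_model(kind, X, Y, seed=3).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            make_model("mystery")


class TestScreenModels:
    def test_baseline_never_discarded_and_weak_models_are(self):
        # exactly linear data: trees cannot beat the linear baseline
        X, Y = _linear_data(n=150, noise=0.0)
        surviving, stats = screen_models(["lr", "dt"], X, Y, seed=0)
        assert "lr" in surviving
        assert stats["dt"]["cv_r2_mean"] < stats["lr"]["cv_r2_mean"]
        assert "dt" not in surviving

    def test_high_fold_variability_discarded(self):
        X, Y = _linear_data(n=150, noise=0.05)
        # a zero SD threshold trips the variability rule for any real model
        surviving, stats = screen_models(["lr", "rf"], X, Y,
                                         sd_threshold=0.0, seed=0)
        assert surviving == ["lr"]
        assert stats["rf"]["cv_r2_sd"] > 0

    def test_baseline_required(self):
        X, Y = _linear_data(n=60)
        with pytest.raises(ValueError):
            screen_models(["rf"], X, Y)


class TestSearchHyperparams:
    def test_single_point_space(self):
        X, Y = _linear_data(n=60)
        best, model, history = search_hyperparams(
            "svm", X, Y, space={"kernel": ("cat", ["linear"])}, n_iter=50,
            folds=3, seed=0)
        assert best == {"kernel": "linear"}
        assert len(history) == 1

    def test_samples_respect_bounds(self):
        X, Y = _linear_data(n=60)
        _, _, history = search_hyperparams("svm", X, Y, n_iter=10, folds=2, seed=1)
        for params, _ in history:
            assert 0.01 <= params["C"] <= 5.0
            assert 0.0 <= params["epsilon"] <= 5.0
            assert 1 <= params["degree"] <= 9
            assert params["kernel"] in ("linear", "poly", "rbf", "sigmoid")

    def test_best_at_least_first(self):
        X, Y = _linear_data(n=60)
        best, _, history = search_hyperparams("svm", X, Y, n_iter=8, folds=2, seed=2)
        best_score = max(s for _, s in history)
        assert best_score >= history[0][1]
        assert best in [p for p, s in history if s == best_score]

    def test_empty_space_rejected(self):
        X, Y = _linear_data(n=30)
        with pytest.raises(ValueError):
            search_hyperparams("svm", X, Y, space={}, n_iter=5)

    def test_spaces_cover_tuned_families(self):
        assert set(SEARCH_SPACES) == {"rf", "xgb", "gb", "svm"}


class TestEvaluateModel:
    class _Echo:
        def __init__(self, shift=0.0):
            self.shift = shift

        def predict(self, X):
            return X[:, :2] + self.shift

    def test_perfect_predictions(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        rep = evaluate_model(self._Echo(), X, X[:, :2])
        assert rep.r2 == pytest.approx(1.0)
        assert rep.mse == pytest.approx(0.0, abs=1e-15)
        assert rep.mae == pytest.approx(0.0, abs=1e-15)

    def test_half_shift_on_one_output(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        Y = X[:, :2].copy()

        class OneOff:
            def predict(self, Xq):
                p = Xq[:, :2].copy()
                p[:, 0] += 0.5
                return p

        rep = evaluate_model(OneOff(), X, Y)
        assert rep.mae == pytest.approx(0.25)
        assert rep.mse == pytest.approx(0.125)

    def test_mean_predictor_r2_zero(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(400, 2))

        class Mean:
            def predict(self, Xq):
                return np.tile(Y.mean(axis=0), (len(Xq), 1))

        rep = evaluate_model(Mean(), np.zeros((400, 1)), Y)
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_metric_sanity(self):
        X, Y = _linear_data(n=80, noise=0.5)
        model = train_model("dt", X, Y, {"max_depth": 2})
        rep = evaluate_model(model, X, Y)
        assert rep.mse >= 0 and rep.mae >= 0 and rep.r2 <= 1

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError):
            evaluate_model(self._Echo(), np.zeros((0, 2)), np.zeros((0, 2)))


class TestSurrogateRegressor:
    def test_sklearn_interface(self):
        X, Y = _linear_data()
        reg = SurrogateRegressor(kind="lr")
        assert reg.get_params()["kind"] == "lr"
        reg.fit(X, Y)
        assert reg.predict(X).shape == Y.shape
        assert reg.report(X, Y).r2 == pytest.approx(1.0, abs=1e-10)

    def test_tuning_path(self):
        X, Y = _linear_data(n=80, noise=0.05)
        reg = SurrogateRegressor(kind="svm", tune=True, n_iter=4, cv_folds=2, seed=0)
        reg.fit(X, Y)
        assert reg.best_params_ is not None
        assert len(reg.search_history_) <= 4

    def test_clone_compatible(self):
        from sklearn.base import clone

        reg = SurrogateRegressor(kind="rf", seed=7)
        assert clone(reg).get_params() == reg.get_params()
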
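"""Model families: null, linear benchmark, TF-IDF elastic net, encoders."""

import numpy as np
import pytest

from icbtpred.metrics import rmse
from icbtpred.models import (EncoderModel, HyperparameterGrid, MeanPredictor,
                             ModelInputs, SymptomLinearModel,
                             TfidfElasticNetModel, WindowedEncoderModel,
                             make_model)
from icbtpred.nn import EncoderSpec


def make_inputs(texts=None, features=None, n=None):
    if texts is None:
        texts = [""] * n
    if features is None:
        features = np.zeros((len(texts), 9))
    return ModelInputs(texts=list(texts),
                       bow_tokens=[t.split() for t in texts],
                       features=np.asarray(features, float))


class TestMeanPredictor:
    def test_predicts_training_mean(self):
        model = MeanPredictor().fit(make_inputs(n=2), [0.2, 0.4])
        assert np.allclose(model.predict(make_inputs(n=5)), 0.3)

    def test_constant_outcomes_give_zero_training_rmse(self):
        inputs = make_inputs(n=4)
        model = MeanPredictor().fit(inputs, [0.7] * 4)
        assert rmse(model.predict(inputs), [0.7] * 4) == 0.0

    def test_prediction_ignores_test_features(self, rng):
        model = MeanPredictor().fit(make_inputs(n=3), [0.1, 0.2, 0.3])
        a = model.predict(make_inputs(features=rng.normal(size=(4, 9)), n=4))
        b = model.predict(make_inputs(features=rng.normal(size=(4, 9)), n=4))
        assert np.array_equal(a, b)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MeanPredictor().fit(make_inputs(n=0), [])


class TestSymptomLinearModel:
    def test_recovers_exactly_linear_target(self, rng):
        features = rng.random((40, 9))
        features[:, 6:] = np.eye(3)[rng.integers(0, 3, size=40)]
        y = 0.1 + 0.7 * features[:, 5]  # linear in the week-4 column
        model = SymptomLinearModel().fit(make_inputs(features=features, n=40), y)
        test_feats = rng.random((10, 9))
        test_feats[:, 6:] = np.eye(3)[rng.integers(0, 3, size=10)]
        pred = model.predict(make_inputs(features=test_feats, n=10))
        assert rmse(pred, 0.1 + 0.7 * test_feats[:, 5]) < 1e-8

    def test_training_point_predicted_at_fitted_value(self, rng):
        features = rng.random((30, 9))
        y = rng.random(30)
        model = SymptomLinearModel().fit(make_inputs(features=features, n=30), y)
        fitted = model.predict(make_inputs(features=features, n=30))
        dup = model.predict(make_inputs(features=features[[4]], n=1))
        assert dup[0] == pytest.approx(fitted[4], abs=1e-12)

    def test_matches_normal_equations_on_toy_design(self):
        """Minimum-norm least squares agrees with a pseudo-inverse solution
        of the normal equations on a 5-patient design."""
        features = np.array([
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 1, 0, 0],
            [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0, 1, 0],
            [0.2, 0.2, 0.2, 0.3, 0.3, 0.3, 0, 0, 1],
            [0.5, 0.4, 0.6, 0.5, 0.4, 0.6, 1, 0, 0],
            [0.7, 0.7, 0.1, 0.2, 0.9, 0.8, 0, 1, 0],
        ])
        y = np.array([0.3, 0.5, 0.2, 0.4, 0.6])
        X = np.column_stack([np.ones(5), features])
        beta_oracle = np.linalg.pinv(X.T @ X) @ X.T @ y
        model = SymptomLinearModel().fit(make_inputs(features=features, n=5), y)
        pred = model.predict(make_inputs(features=features, n=5))
        assert np.allclose(pred, X @ beta_oracle, atol=1e-8)


def tfidf_oracle(docs: list[list[str]], max_df: float = 0.8):
    """Independent tf-idf computation written out longhand:
    idf(t) = ln((1+n)/(1+df(t))) + 1, rows L2-normalised."""
    n = len(docs)
    vocab = sorted({t for d in docs for t in d})
    df = {t: sum(t in d for d in docs) for t in vocab}
    vocab = [t for t in vocab if df[t] / n <= max_df]
    rows = []
    for d in docs:
        tf = np.array([d.count(t) for t in vocab], float)
        idf = np.array([np.log((1 + n) / (1 + df[t])) + 1 for t in vocab])
        w = tf * idf
        norm = np.linalg.norm(w)
        rows.append(w / norm if norm > 0 else w)
    return vocab, np.array(rows)


def elasticnet_objective(X, y, w, b, alpha, l1_ratio):
    n = len(y)
    resid = y - X @ w - b
    return (resid @ resid / (2 * n)
            + alpha * (l1_ratio * np.abs(w).sum()
                       + 0.5 * (1 - l1_ratio) * w @ w))


def elasticnet_cd_oracle(X, y, alpha, l1_ratio, n_iter=3000):
    """Brute-force coordinate descent on the elastic-net objective."""
    n, p = X.shape
    w = np.zeros(p)
    b = y.mean()
    col_sq = (X**2).sum(axis=0) / n
    for _ in range(n_iter):
        b = (y - X @ w).mean()
        r = y - X @ w - b
        for j in range(p):
            rho = (X[:, j] @ r) / n + col_sq[j] * w[j]
            denom = col_sq[j] + alpha * (1 - l1_ratio)
            new = np.sign(rho) * max(abs(rho) - alpha * l1_ratio, 0.0) / denom
            r += X[:, j] * (w[j] - new)
            w[j] = new
    return w, b


class TestTfidfElasticNet:
    def test_term_in_more_than_80pct_of_documents_discarded(self):
        texts = ["common unique%d" % i for i in range(10)]
        texts = [t if i == 0 else t + " common" for i, t in enumerate(texts)]
        model = TfidfElasticNetModel(n_features=50, alpha=0.01)
        model.fit(make_inputs(texts=texts), np.linspace(0, 1, 10))
        assert "common" not in model.vectorizer_.vocabulary_

    def test_single_document_weights_proportional_to_term_frequency(self):
        model = TfidfElasticNetModel(n_features=10, alpha=0.01)
        model.fit(make_inputs(texts=["a a a b"]), [0.5])
        X = model.build_matrix(make_inputs(texts=["a a a b"]), fit=False).toarray()
        a_idx = model.vectorizer_.vocabulary_["a"]
        b_idx = model.vectorizer_.vocabulary_["b"]
        assert X[0, a_idx] == pytest.approx(3 * X[0, b_idx])

    def test_three_document_weights_match_longhand_tfidf(self):
        texts = ["sleep poor sleep", "mood low mood low energy", "sleep good"]
        model = TfidfElasticNetModel(n_features=50, alpha=0.01)
        model.fit(make_inputs(texts=texts), [0.1, 0.5, 0.9])
        X = model.build_matrix(make_inputs(texts=texts), fit=False).toarray()
        vocab, expected = tfidf_oracle([t.split() for t in texts])
        for j, term in enumerate(vocab):
            col = model.vectorizer_.vocabulary_[term]
            assert np.allclose(X[:, col], expected[:, j], atol=1e-12), term

    def test_huge_alpha_shrinks_to_intercept_only(self, rng):
        texts = ["tok%d tok%d" % (i, i + 1) for i in range(20)]
        y = rng.random(20)
        model = TfidfElasticNetModel(n_features=50, alpha=1e6)
        model.fit(make_inputs(texts=texts), y)
        pred = model.predict(make_inputs(texts=texts))
        assert np.allclose(pred, y.mean(), atol=1e-8)

    def test_tiny_alpha_approaches_least_squares_on_full_rank_toy(self, rng):
        """The regressor behind the text model reduces to least squares in
        the no-penalty limit (checked on a plain full-rank design, since a
        token-count realisation of an arbitrary design is impractical)."""
        X = rng.normal(size=(30, 3))
        y = X @ np.array([0.5, -0.3, 0.2]) + 0.1
        from sklearn.linear_model import ElasticNet
        en = ElasticNet(alpha=1e-8, l1_ratio=0.5, max_iter=50000).fit(X, y)
        beta = np.linalg.lstsq(np.column_stack([np.ones(30), X]), y, rcond=None)[0]
        assert np.allclose(en.predict(X),
                           np.column_stack([np.ones(30), X]) @ beta, atol=1e-4)

    def test_objective_matches_coordinate_descent_oracle(self, rng):
        """The fitted elastic net reaches the same objective value as an
        independent brute-force coordinate-descent solver on a 10x3 design."""
        from sklearn.linear_model import ElasticNet
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        alpha, l1_ratio = 0.3, 0.5
        en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50000,
                        tol=1e-12).fit(X, y)
        w_o, b_o = elasticnet_cd_oracle(X, y, alpha, l1_ratio)
        f_pkg = elasticnet_objective(X, y, en.coef_, en.intercept_, alpha, l1_ratio)
        f_oracle = elasticnet_objective(X, y, w_o, b_o, alpha, l1_ratio)
        assert f_pkg == pytest.approx(f_oracle, abs=1e-6)

    def test_fused_design_width_is_text_features_plus_nine(self):
        for n_features in (5, 12):
            texts = ["w%d x%d y%d z%d q%d" % (i, i+1, i+2, i+3, i+4) for i in range(20)]
            model = TfidfElasticNetModel(n_features=n_features, alpha=0.1,
                                         use_symptoms=True)
            inputs = make_inputs(texts=texts)
            model.fit(inputs, np.linspace(0, 1, 20))
            X = model.build_matrix(inputs, fit=False)
            assert X.shape[1] == len(model.vectorizer_.vocabulary_) + 9
            assert len(model.vectorizer_.vocabulary_) <= n_features

    def test_zeroed_text_reduces_to_symptom_only_model(self, rng):
        """With blank documents the fused model must equal an elastic net on
        the symptom block alone."""
        from sklearn.linear_model import ElasticNet
        features = rng.random((25, 9))
        y = rng.random(25)
        fused = TfidfElasticNetModel(n_features=10, alpha=0.05, l1_ratio=0.5,
                                     use_symptoms=True)
        texts = ["filler"] * 25   # single shared token -> df = 100% -> dropped
        inputs = make_inputs(texts=texts, features=features)
        fused.fit(inputs, y)
        direct = ElasticNet(alpha=0.05, l1_ratio=0.5, max_iter=5000).fit(features, y)
        assert np.allclose(fused.predict(inputs), direct.predict(features),
                           atol=1e-6)

    def test_empty_corpus_rejected(self):
        model = TfidfElasticNetModel()
        with pytest.raises(ValueError, match="empty corpus"):
            model.fit(make_inputs(texts=["", ""]), [0.1, 0.2])


class TestEncoderModels:
    def test_desk_scale_signal_recovery_beats_dummy(self, rng):
        """A small encoder trained on token windows with a planted frequency
        signal predicts better than the outcome mean on held-out patients."""
        vocab = [f"w{i}" for i in range(40)] + [f"sig{i}" for i in range(8)]
        n = 120
        z = rng.normal(size=n)
        texts = []
        y = 0.5 + 0.15 * np.tanh(z)
        for i in range(n):
            logits = np.zeros(48)
            logits[40:] = 2.0 * z[i]
            p = np.exp(logits - logits.max())
            p /= p.sum()
            texts.append(" ".join(rng.choice(vocab, size=60, p=p)))
        inputs = make_inputs(texts=texts)
        spec = EncoderSpec(embedding_dim=16, n_layers=1, n_heads=2)
        model = EncoderModel(spec=spec, learning_rate=3e-3, batch_size=16,
                             epochs=6, seed=0)
        tr, te = np.arange(90), np.arange(90, 120)
        model.fit(inputs.subset(tr), y[tr])
        pred = model.predict(inputs.subset(te))
        dummy_rmse = rmse(np.full(30, y[tr].mean()), y[te])
        assert rmse(pred, y[te]) < dummy_rmse

    def test_windowed_prediction_is_mean_of_submodels(self, rng):
        texts = [" ".join(rng.choice([f"w{i}" for i in range(20)], size=30))
                 for _ in range(8)]
        inputs = make_inputs(texts=texts)
        spec = EncoderSpec(embedding_dim=8, n_layers=1, n_heads=2)
        model = WindowedEncoderModel(spec=spec, epochs=1, batch_size=4, seed=0)
        model.fit(inputs, rng.random(8))
        subs = [net.predict(w) for net, w in
                zip(model.nets_, model._window_lists(inputs))]
        assert np.allclose(model.predict(inputs), np.mean(subs, axis=0),
                           atol=1e-12)

    def test_windowed_constant_submodels_predict_the_constant(self, rng):
        texts = ["alpha beta"] * 6
        inputs = make_inputs(texts=texts)
        spec = EncoderSpec(embedding_dim=8, n_layers=1, n_heads=2)
        model = WindowedEncoderModel(spec=spec, epochs=1, batch_size=4, seed=0)
        model.fit(inputs, rng.random(6))
        for net in model.nets_:  # force each head to output exactly 0.42
            for p in net.params():
                p.data[...] = 0.0
            net.head_out.b.data[...] = 0.42
        assert np.allclose(model.predict(inputs), 0.42, atol=1e-6)

    def test_windowed_fusion_head_width_per_submodel(self, rng):
        texts = ["tok tok tok"] * 6
        inputs = make_inputs(texts=texts, features=rng.random((6, 9)))
        spec = EncoderSpec(embedding_dim=16, n_layers=1, n_heads=2)
        model = WindowedEncoderModel(spec=spec, use_symptoms=True, epochs=1,
                                     batch_size=4, seed=0)
        model.fit(inputs, rng.random(6))
        assert all(net.head_input_dim == 16 + 9 for net in model.nets_)

    def test_full_scale_fusion_spec_constructs_777_head(self):
        model = EncoderModel(spec=EncoderSpec(embedding_dim=768, n_heads=12),
                             use_symptoms=True)
        from icbtpred.nn.transformer import TransformerRegressor
        from dataclasses import replace
        net = TransformerRegressor(replace(model.spec, vocab_size=100), seed=0)
        assert net.head_input_dim == 777


class TestGridAndRegistry:
    def test_full_grid_enumerates_published_configurations(self):
        grid = HyperparameterGrid.full_grid()
        tfidf = grid.configs("tfidf")
        assert len(tfidf) == 2 * 2 * 4 * 3
        assert tfidf[0] == {"n_features": 500, "ngram_max": 1, "alpha": 3.0,
                            "l1_ratio": 0.2}
        enc = grid.configs("encoder")
        assert [c["learning_rate"] for c in enc] == [5e-5, 2e-5]
        assert enc[0]["batch_size"] == 32 and enc[0]["epochs"] == 4
        wnd = grid.configs("windowed")
        assert [c["learning_rate"] for c in wnd] == [2e-5]
        assert wnd[0]["batch_size"] == 8 and wnd[0]["epochs"] == 5

    def test_registry_instantiates_every_family(self):
        for family in ("dummy", "linear", "tfidf", "tfidf_sym", "encoder",
                       "encoder_sym", "windowed", "windowed_sym"):
            cfgs = HyperparameterGrid.desk_grid().configs(family)
            model = make_model(family, cfgs[0])
            assert hasattr(model, "fit") and hasattr(model, "predict")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_model("bagging")


class TestPersistence:
    def test_fitted_models_round_trip_through_bundle(self, rng, tmp_path):
        from icbtpred.models import load_model, save_model

        texts = [" ".join(rng.choice([f"w{i}" for i in range(30)], size=20))
                 for _ in range(25)]
        inputs = make_inputs(texts=texts, features=rng.random((25, 9)))
        y = rng.random(25)
        spec = EncoderSpec(embedding_dim=8, n_layers=1, n_heads=2)
        models = [MeanPredictor().fit(inputs, y),
                  SymptomLinearModel().fit(inputs, y),
                  TfidfElasticNetModel(n_features=20, alpha=0.1).fit(inputs, y),
                  EncoderModel(spec=spec, epochs=1, batch_size=8,
                               seed=0).fit(inputs, y)]
        for i, model in enumerate(models):
            path = tmp_path / f"m{i}.bundle"
            save_model(model, path)
            back = load_model(path)
            assert np.allclose(back.predict(inputs), model.predict(inputs))

    def test_foreign_file_rejected(self, tmp_path):
        import pickle

        from icbtpred.models import load_model
        path = tmp_path / "x.bundle"
        path.write_bytes(pickle.dumps({"something": "else"}))
        with pytest.raises(ValueError, match="bundle"):
            load_model(path)
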
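"""Model tracks: gradient boosting, CNN-LSTM, embedding pooling."""

import numpy as np
import pandas as pd
import pytest

from ltrlearn.features import FeatureMatrix, one_hot_encode
from ltrlearn.models import (
    CnnLstmClassifier,
    EmbedderContractError,
    KmerHashEmbedder,
    PooledHeadClassifier,
    build_cnn_lstm,
    build_pooled_head,
    class_weights,
    grid_search_cv,
    train_gbdt,
    window_pool_embeddings,
)
from ltrlearn.nn import TrainConfig


def _feature_matrix(values, kind="tfidf"):
    arr = np.asarray(values, dtype=float)
    norms = np.linalg.norm(arr, axis=1, keepdims=True)
    norms[norms == 0] = 1
    return FeatureMatrix(pd.DataFrame(arr / norms), kind=kind)


@pytest.fixture
def separable_features(rng):
    """Feature 0 carries all the signal, feature 1 is noise."""
    n = 80
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y + rng.normal(0, 0.05, n), rng.normal(0, 1, n)])
    return _feature_matrix(X), y


class TestClassWeights:
    def test_balanced_classes_get_unit_weights(self):
        w = class_weights([0] * 10 + [1] * 10)
        assert w == {0: 1.0, 1: 1.0}

    def test_imbalanced_inverse_frequency(self):
        w = class_weights([0] * 90 + [1] * 10)
        assert w[0] == pytest.approx(100 / (2 * 90))
        assert w[1] == pytest.approx(5.0)

    def test_frequency_weighted_mean_is_one(self, rng):
        labels = rng.choice(["a", "b", "c"], p=[0.6, 0.3, 0.1], size=500)
        w = class_weights(labels)
        mean = np.mean([w[l] for l in labels])
        assert mean == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestGbdt:
    def test_separable_task_perfect_training_f1(self, separable_features):
        fm, y = separable_features
        handle = train_gbdt(fm, y, seed=0)
        assert handle.fitted and handle.kind == "gbdt"
        assert np.array_equal(handle.model.predict(fm.values), y)

    def test_seed_determinism(self, separable_features):
        fm, y = separable_features
        p1 = train_gbdt(fm, y, seed=3).model.predict_proba(fm.values)
        p2 = train_gbdt(fm, y, seed=3).model.predict_proba(fm.values)
        assert np.array_equal(p1, p2)

    def test_single_class_labels_rejected(self, separable_features):
        fm, _ = separable_features
        with pytest.raises(ValueError):
            train_gbdt(fm, np.zeros(len(fm.values)), seed=0)


class TestGridSearch:
    def test_single_cell_returned(self, separable_features):
        fm, y = separable_features
        res = grid_search_cv(fm, y, {"gbdt": {"n_estimators": [10]}}, k_folds=4, seed=0)
        assert res.best_kind == "gbdt" and res.best_params == {"n_estimators": 10}

    def test_table_has_grid_times_fold_rows(self, separable_features):
        fm, y = separable_features
        grid = {"gbdt": {"n_estimators": [5, 10], "max_depth": [1, 2]}}
        res = grid_search_cv(fm, y, grid, k_folds=3, seed=0)
        assert len(res.table) == 4 * 3

    def test_crippled_configuration_loses(self, rng):
        # additive two-feature rule: a single depth-1 stump cannot express it
        X = rng.uniform(size=(300, 2))
        y = (X[:, 0] + X[:, 1] > 1).astype(int)
        fm = _feature_matrix(X)
        grid = {"gbdt": [{"n_estimators": [100], "max_depth": [3]},
                         {"n_estimators": [1], "max_depth": [1], "learning_rate": [1e-4]}]}
        res = grid_search_cv(fm, y, grid, k_folds=4, seed=0)
        assert res.best_params["n_estimators"] == 100

    def test_excessive_folds_rejected(self, separable_features):
        fm, y = separable_features
        with pytest.raises(ValueError):
            grid_search_cv(fm, y, {"gbdt": {}}, k_folds=len(y), seed=0)


class TestWindowPooling:
    def test_short_sequence_single_call(self):
        calls = []
        embedder = lambda s: (calls.append(s), np.ones(4))[1]
        v = window_pool_embeddings("ACGT" * 100, embedder, window=510, stride=170)
        assert calls == ["ACGT" * 100]
        assert np.array_equal(v, np.ones(4))

    def test_constant_embedder_mean_identity(self, random_sequences):
        seq = random_sequences(1, 1700)[0]
        v = window_pool_embeddings(seq, lambda s: np.array([3.0, -1.0]), window=510, stride=170)
        assert np.allclose(v, [3.0, -1.0])

    @pytest.mark.parametrize("L", [510, 680, 1020, 1021, 1500])
    def test_window_count_matches_enumeration(self, L, random_sequences):
        seq = random_sequences(1, L)[0]
        calls = []
        embedder = lambda s: (calls.append(len(s)), np.zeros(3))[1]
        window_pool_embeddings(seq, embedder, window=510, stride=170)
        if L <= 510:
            expected = 1
        else:
            starts = list(range(0, L - 510 + 1, 170))
            if starts[-1] + 510 < L:
                starts.append(L - 510)
            expected = len(starts)
        assert len(calls) == expected
        assert all(c == min(510, L) for c in calls)

    def test_varying_dimension_rejected(self, random_sequences):
        seq = random_sequences(1, 1200)[0]
        state = {"n": 0}

        def bad(s):
            state["n"] += 1
            return np.zeros(3 + state["n"])

        with pytest.raises(EmbedderContractError):
            window_pool_embeddings(seq, bad, window=510, stride=170)

    def test_kmer_hash_embedder_deterministic(self):
        e1, e2 = KmerHashEmbedder(dim=32, seed=5), KmerHashEmbedder(dim=32, seed=5)
        assert np.array_equal(e1("ACGTACGTAC"), e2("ACGTACGTAC"))
        assert not np.array_equal(KmerHashEmbedder(dim=32, seed=6)("ACGTACGTAC"),
                                  e1("ACGTACGTAC"))


class TestCnnLstm:
    def test_output_shapes_binary_and_family(self):
        h_bin = build_cnn_lstm(n_filters=4, lstm_units=4, L_max=64, task="ltr_detection")
        assert h_bin.kind == "cnn_lstm" and not h_bin.fitted
        net = h_bin.model.build_net(1)
        out, _ = net.forward(np.zeros((3, 64, 4)), np.ones((3, 64), dtype=bool))
        assert out.shape == (3, 1)
        h_fam = build_cnn_lstm(n_filters=4, lstm_units=4, L_max=64, task="family")
        net15 = h_fam.model.build_net(15)
        out, _ = net15.forward(np.zeros((2, 64, 4)), np.ones((2, 64), dtype=bool))
        assert out.shape == (2, 15)

    def test_parameter_count_closed_form(self):
        F, W, H, O = 8, 5, 6, 1
        net = build_cnn_lstm(n_filters=F, filter_width=W, lstm_units=H,
                             L_max=64).model.build_net(O)
        expected = F * (4 * W + 1) + 4 * H * (F + H + 1) + H * O + O
        assert net.n_parameters() == expected

    def test_all_pad_input_gives_bias_only_response(self):
        net = build_cnn_lstm(n_filters=4, lstm_units=4, L_max=32).model.build_net(1)
        out, _ = net.forward(np.zeros((2, 32, 4)), np.zeros((2, 32), dtype=bool))
        assert np.allclose(out, net.params["bo"])

    def test_trains_on_planted_signal(self, rng):
        # positives carry a fixed 10-mer, negatives are pure random
        bases = np.array(list("ACGT"))
        def seq(L): return "".join(rng.choice(bases, size=L))
        pos = []
        for _ in range(150):
            s = list(seq(120))
            s[40:50] = list("ACGTACGTAC")
            pos.append("".join(s))
        neg = [seq(120) for _ in range(150)]
        X = pos + neg
        y = np.array([1] * 150 + [0] * 150)
        order = rng.permutation(300)
        tr, te = order[:240], order[240:]
        clf = CnnLstmClassifier(n_filters=8, filter_width=12, pool_size=64, lstm_units=8,
                                L_max=128, lr=5e-3, epochs=20, patience=5, seed=0)
        clf.fit([X[i] for i in tr], y[tr])
        from ltrlearn.evaluate import compute_metrics

        f1 = compute_metrics(y[te], clf.predict([X[i] for i in te])).f1
        assert f1 >= 0.9
        assert len(clf.history_["train_loss"]) <= 20

    def test_early_stopping_halts_within_patience(self, rng):
        X = ["ACGT" * 32] * 60
        y = rng.integers(0, 2, 60)  # unlearnable: loss cannot improve for long
        clf = CnnLstmClassifier(n_filters=4, lstm_units=4, L_max=128, pool_size=64,
                                epochs=15, patience=2, seed=0)
        clf.fit(X, y)
        h = clf.history_
        best = int(np.argmin(h["val_loss"]))
        assert len(h["val_loss"]) - 1 - best <= 2

    def test_seed_reproducibility(self, random_sequences):
        seqs = [s.sequence for s in random_sequences(40, 100)]
        y = np.array([0, 1] * 20)
        kw = dict(n_filters=4, lstm_units=4, L_max=128, pool_size=64, epochs=4,
                  patience=2, seed=9)
        m1 = CnnLstmClassifier(**kw).fit(seqs, y).decision_function(seqs)
        m2 = CnnLstmClassifier(**kw).fit(seqs, y).decision_function(seqs)
        assert np.array_equal(m1, m2)


class TestPooledHead:
    def test_build_validates_input_dim(self):
        with pytest.raises(ValueError):
            build_pooled_head(2)
        handle = build_pooled_head(64, task="family")
        assert handle.kind == "pooled_head"

    def test_trains_on_separable_embeddings(self, rng):
        # classes point along distinct directions, as a k-mer-content
        # embedder produces for class-distinct composition
        n, d = 400, 64
        y = np.repeat([0, 1], n // 2)
        dirs = rng.normal(size=(2, d))
        V = dirs[y] + rng.normal(0, 0.3, size=(n, d))
        order = rng.permutation(n)
        tr, te = order[:320], order[320:]
        clf = PooledHeadClassifier(epochs=30, patience=8, lr=3e-3, seed=0)
        clf.fit(V[tr], y[tr])
        from ltrlearn.evaluate import compute_metrics

        f1 = compute_metrics(y[te], clf.predict(V[te])).f1
        assert f1 >= 0.9

    def test_seed_determinism(self, rng):
        V = rng.normal(size=(40, 16))
        y = np.array([0, 1] * 20)
        kw = dict(epochs=3, patience=1, seed=4)
        p1 = PooledHeadClassifier(**kw).fit(V, y).decision_function(V)
        p2 = PooledHeadClassifier(**kw).fit(V, y).decision_function(V)
        assert np.array_equal(p1, p2)


class TestTrainConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(patience=15, epochs=15)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(loss="hinge")
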
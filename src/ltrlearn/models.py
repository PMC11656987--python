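"""Trainable model tracks.

Two trainable tracks cover the three classification tasks (LTR
detection, superfamily, family):

* ``train_gbdt`` / :func:`make_tfbs_pipeline` -- a gradient-boosted
  decision-tree ensemble over TF-IDF-weighted TFBS occurrence vectors;
* :class:`CnnLstmClassifier` -- a Conv1D/max-pool/LSTM network over
  one-hot encoded sequences (padded and masked to a fixed input length);

plus the backend-agnostic windowed-embedding path: any embedder obeying
the contract "sequence of at most `window` bases -> fixed-length vector"
can be average-pooled along the sequence with
:func:`window_pool_embeddings` and classified by the small convolutional
head (:class:`PooledHeadClassifier`, 32 filters of width 3 -> dense 32).
The default offline embedder is a deterministic k-mer hash projector.

All estimators follow sklearn conventions (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, fitted attributes with a trailing
underscore) and are reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix, OneHotBatch, PwmMotifCounter, one_hot_encode, kmer_tokenize
from .nn import CnnLstmNet, PooledHeadNet, TrainConfig, fit_network

DEFAULT_FAMILIES = (
    # configuration default: 9 Ty1/Copia + 6 Ty3/Gypsy lineages
    "Ale", "Alesia", "Angela", "Athila", "Bianca", "CRM", "Galadriel", "Ikeros",
    "Ivana", "Reina", "Retand", "SIRE", "TAR", "Tekay", "Tork",
)

TASKS = ("ltr_detection", "superfamily", "family")


@dataclass
class ModelHandle:
    """A uniform wrapper around a fitted (or buildable) model track."""

    kind: str  # gbdt | cnn_lstm | pooled_head
    task: str
    model: object
    hyperparams: dict = dataclass_field(default_factory=dict)
    seed: int = 0
    class_names: list = dataclass_field(default_factory=list)
    fitted: bool = False

    def predict(self, X):
        return self.model.predict(X)

    def predict_proba(self, X):
        return self.model.predict_proba(X)


def class_weights(labels) -> dict:
    """Inverse-frequency class weights, weight_c = N / (K * n_c).

    The frequency-weighted mean of the weights is 1, so the weighted loss
    stays on the same scale as the unweighted one.
    """
    labels = list(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("class weighting needs at least 2 classes")
    if np.any(counts == 0):
        raise ValueError("empty class")
    N, K = len(labels), len(classes)
    return {c: N / (K * n) for c, n in zip(classes, counts)}


# ---------------------------------------------------------------------------
# TFBS track (gradient boosting)


def train_gbdt(features: FeatureMatrix, labels, hyperparams: dict | None = None, seed: int = 0,
               task: str = "ltr_detection") -> ModelHandle:
    """Fit the gradient-boosted ensemble on TF-IDF features.

    The fitted sklearn model exposes per-tree structure via
    ``model.estimators_`` (needed by the exact tree attribution path).
    """
    y = np.asarray(list(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if len(X) != len(y):
        raise ValueError("feature rows and labels are misaligned")
    hp = {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.1}
    hp.update(hyperparams or {})
    model = GradientBoostingClassifier(random_state=seed, **hp)
    model.fit(X, y)
    return ModelHandle(kind="gbdt", task=task, model=model, hyperparams=hp, seed=seed,
                       class_names=list(model.classes_), fitted=True)


def make_tfbs_pipeline(motifs, hyperparams: dict | None = None, seed: int = 0,
                       rel_threshold: float = 0.8) -> Pipeline:
    """Sequences -> PWM counts -> TF-IDF -> gradient boosting pipeline."""
    from sklearn.feature_extraction.text import TfidfTransformer

    hp = {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.1}
    hp.update(hyperparams or {})
    return Pipeline([
        ("counts", PwmMotifCounter(motifs=list(motifs), rel_threshold=rel_threshold)),
        ("tfidf", TfidfTransformer(norm="l2", smooth_idf=True)),
        ("gbc", GradientBoostingClassifier(random_state=seed, **hp)),
    ])


_GRID_ESTIMATORS = {
    "gbdt": lambda seed, hp: GradientBoostingClassifier(random_state=seed, **hp),
    "rf": lambda seed, hp: RandomForestClassifier(random_state=seed, **hp),
    "mlp": lambda seed, hp: MLPClassifier(random_state=seed, max_iter=500, **hp),
}


@dataclass
class GridSearchResult:
    best_kind: str
    best_params: dict
    best_score: float
    table: pd.DataFrame


def grid_search_cv(features, labels, model_grid: dict, k_folds: int = 5, seed: int = 0) -> GridSearchResult:
    """Exhaustive grid x stratified k-fold model selection by mean F1.

    ``model_grid`` maps a model kind (gbdt / rf / mlp) to a sklearn-style
    parameter grid.  The returned table has one row per (kind, cell, fold).
    """
    y = np.asarray(list(labels))
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(f"k_folds={k_folds} exceeds the smallest class size ({counts.min()})")
    average = "binary" if len(classes) == 2 else "weighted"
    pos_label = classes.max() if len(classes) == 2 else None
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rows = []
    for kind, grid in model_grid.items():
        if kind not in _GRID_ESTIMATORS:
            raise ValueError(f"unknown model kind {kind!r}")
        for params in ParameterGrid(grid):
            for fold, (tr, te) in enumerate(skf.split(X, y)):
                est = _GRID_ESTIMATORS[kind](seed, params)
                est.fit(X[tr], y[tr])
                pred = est.predict(X[te])
                if average == "binary":
                    score = f1_score(y[te], pred, average="binary", pos_label=pos_label)
                else:
                    score = f1_score(y[te], pred, average="weighted")
                rows.append({"kind": kind, "params": dict(params), "fold": fold, "f1": score})
    table = pd.DataFrame(rows)
    sums: dict = {}
    for row in rows:
        key = (row["kind"], tuple(sorted(row["params"].items())))
        total, count = sums.get(key, (0.0, 0))
        sums[key] = (total + row["f1"], count + 1)
    best_key, best_score = max(
        ((k, total / count) for k, (total, count) in sums.items()), key=lambda kv: kv[1]
    )
    return GridSearchResult(best_kind=best_key[0], best_params=dict(best_key[1]),
                            best_score=float(best_score), table=table)


# ---------------------------------------------------------------------------
# CNN-LSTM track


class CnnLstmClassifier(BaseEstimator, ClassifierMixin):
    """Conv1D -> max pool -> LSTM -> dense classifier over DNA sequences.

    Accepts raw sequences (strings or LabeledSequence) or a pre-encoded
    :class:`OneHotBatch`.  Binary tasks use one sigmoid output unit;
    multiclass tasks a softmax layer over the classes.  ``class_weight``
    may be None, "balanced" (inverse frequency), or a per-class mapping.

    Default topology: 64 filters of width 12 (spanning typical TFBS motif
    widths so filter->motif mapping stays meaningful), pool 4, 64 LSTM
    units, learning rate 1e-3, input length 4000.
    """

    def __init__(self, n_filters: int = 64, filter_width: int = 12, pool_size: int = 4,
                 lstm_units: int = 64, L_max: int = 4000, lr: float = 1e-3, epochs: int = 15,
                 batch_size: int = 64, patience: int = 3, class_weight=None,
                 validation_fraction: float = 0.1, task: str = "ltr_detection", seed: int = 0,
                 forget_bias: float = 1.0):
        self.forget_bias = forget_bias
        self.n_filters = n_filters
        self.filter_width = filter_width
        self.pool_size = pool_size
        self.lstm_units = lstm_units
        self.L_max = L_max
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.class_weight = class_weight
        self.validation_fraction = validation_fraction
        self.task = task
        self.seed = seed

    def _encode(self, X) -> OneHotBatch:
        if isinstance(X, OneHotBatch):
            return X
        return one_hot_encode(X, L_max=self.L_max)

    def build_net(self, n_outputs: int) -> CnnLstmNet:
        if self.filter_width > self.L_max:
            raise ValueError("filter_width must not exceed L_max")
        return CnnLstmNet(n_filters=self.n_filters, filter_width=self.filter_width,
                          pool_size=self.pool_size, lstm_units=self.lstm_units,
                          n_outputs=n_outputs, seed=self.seed, forget_bias=self.forget_bias)

    def fit(self, X, y, validation=None):
        y = np.asarray(list(y))
        batch = self._encode(X)
        if len(y) != len(batch.array):
            raise ValueError("X and y are misaligned")
        self.classes_ = np.unique(y)
        binary = len(self.classes_) == 2
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        idx = {c: i for i, c in enumerate(self.classes_)}
        y_enc = np.array([idx[v] for v in y], dtype=float if binary else int)
        cw = None
        if self.class_weight == "balanced":
            w = class_weights(y)
            cw = np.array([w[c] for c in self.classes_])
        elif self.class_weight is not None:
            cw = np.array([self.class_weight[c] for c in self.classes_])
        if validation is None:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(y_enc))
            n_val = max(1, int(round(self.validation_fraction * len(y_enc))))
            val_idx, tr_idx = order[:n_val], order[n_val:]
        else:
            Xv, yv = validation
            vbatch = self._encode(Xv)
            yv_enc = np.array([idx[v] for v in yv], dtype=float if binary else int)
            tr_idx = np.arange(len(y_enc))
            val_idx = None
        self.net_ = self.build_net(1 if binary else len(self.classes_))
        cfg = TrainConfig(lr=self.lr, epochs=self.epochs, batch_size=self.batch_size,
                          patience=self.patience, seed=self.seed,
                          loss="binary_ce" if binary else "categorical_ce_weighted",
                          class_weight=cw)
        if val_idx is not None:
            val = (batch.array[val_idx], batch.mask[val_idx], y_enc[val_idx])
        else:
            val = (vbatch.array, vbatch.mask, yv_enc)
        train = (batch.array[tr_idx], batch.mask[tr_idx], y_enc[tr_idx])
        self.history_ = fit_network(self.net_, train, val, cfg)
        self.n_outputs_ = 1 if binary else len(self.classes_)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        batch = self._encode(X)
        outs = []
        for start in range(0, len(batch.array), 256):
            sl = slice(start, start + 256)
            out, _ = self.net_.forward(batch.array[sl], batch.mask[sl])
            outs.append(out)
        margins = np.concatenate(outs, axis=0)
        return margins[:, 0] if self.n_outputs_ == 1 else margins

    def predict_proba(self, X) -> np.ndarray:
        margins = self.decision_function(X)
        if self.n_outputs_ == 1:
            p = 1.0 / (1.0 + np.exp(-margins))
            return np.column_stack([1 - p, p])
        z = margins - margins.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def build_cnn_lstm(n_filters: int = 64, filter_width: int = 12, pool_size: int = 4,
                   lstm_units: int = 64, L_max: int = 4000, task: str = "ltr_detection",
                   seed: int = 0, **kwargs) -> ModelHandle:
    """Build an untrained CNN-LSTM track for a task."""
    n_classes = {"ltr_detection": 2, "superfamily": 2, "family": len(DEFAULT_FAMILIES)}[task]
    clf = CnnLstmClassifier(n_filters=n_filters, filter_width=filter_width, pool_size=pool_size,
                            lstm_units=lstm_units, L_max=L_max, task=task, seed=seed, **kwargs)
    return ModelHandle(kind="cnn_lstm", task=task, model=clf, seed=seed,
                       hyperparams=clf.get_params(), class_names=[], fitted=False)


def train_sequence_model(handle: ModelHandle, train, validation, cfg: TrainConfig | None = None) -> ModelHandle:
    """Train a sequence-model handle; history lands on ``handle.history``."""
    X, y = train
    clf = handle.model
    if cfg is not None:
        clf.set_params(lr=cfg.lr, epochs=cfg.epochs, batch_size=cfg.batch_size,
                       patience=cfg.patience, seed=cfg.seed)
    clf.fit(X, y, validation=validation)
    handle.fitted = True
    handle.class_names = list(clf.classes_)
    handle.history = clf.history_
    return handle


# ---------------------------------------------------------------------------
# windowed-embedding track


class EmbedderContractError(TypeError):
    pass


def window_pool_embeddings(seq, embedder, window: int = 510, stride: int = 170) -> np.ndarray:
    """Average-pooled embedding of a long sequence.

    Windows start at 0 and advance by ``stride``; a final end-anchored
    window is added when the last regular window does not reach the
    sequence end.  Sequences no longer than ``window`` take a single call.
    The element-wise mean of the per-window embeddings is returned.
    """
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    s = seq.sequence if hasattr(seq, "sequence") else str(seq)
    L = len(s)
    if L <= window:
        starts = [0]
        window = min(window, L)
    else:
        starts = list(range(0, L - window + 1, stride))
        if starts[-1] + window < L:
            starts.append(L - window)
    vecs = []
    dim = None
    for start in starts:
        v = np.asarray(embedder(s[start : start + window]), dtype=float).ravel()
        if dim is None:
            dim = v.size
        elif v.size != dim:
            raise EmbedderContractError(
                f"embedder dimension changed between windows ({dim} -> {v.size})"
            )
        vecs.append(v)
    return np.mean(vecs, axis=0)


class KmerHashEmbedder:
    """Deterministic k-mer-hash projector: an offline embedder.

    Each k-mer hashes (keyed blake2b, so stable across processes) to a
    signed coordinate of a ``dim``-vector; the embedding is the signed
    k-mer count profile scaled by 1/sqrt(token count).  Distinct k-mer
    content maps to distinct directions, which is all the pooled head
    needs.
    """

    def __init__(self, dim: int = 768, k: int = 6, seed: int = 0):
        self.dim, self.k, self.seed = dim, k, seed

    def __call__(self, seq: str) -> np.ndarray:
        tokens = kmer_tokenize(seq, self.k).tokens
        v = np.zeros(self.dim)
        key = str(self.seed).encode()
        for t in tokens:
            digest = hashlib.blake2b(t.encode(), key=key, digest_size=8).digest()
            h = int.from_bytes(digest, "little")
            v[h % self.dim] += 1.0 if (h >> 62) & 1 else -1.0
        if tokens:
            v /= np.sqrt(len(tokens))
        return v


class PooledHeadClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional head over pooled embedding vectors.

    1-D convolution (32 filters of width 3) along the embedding
    coordinates, global max pooling, a dense layer of size 32, and a
    sigmoid (binary) or softmax (family) output.
    """

    def __init__(self, n_filters: int = 32, filter_width: int = 3, dense_units: int = 32,
                 lr: float = 1e-3, epochs: int = 15, batch_size: int = 64, patience: int = 3,
                 validation_fraction: float = 0.1, class_weight=None, task: str = "ltr_detection",
                 seed: int = 0):
        self.n_filters = n_filters
        self.filter_width = filter_width
        self.dense_units = dense_units
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.class_weight = class_weight
        self.task = task
        self.seed = seed

    def fit(self, V, y, validation=None):
        V = np.asarray(V, dtype=float)
        if V.ndim != 2 or V.shape[1] < 3:
            raise ValueError("V must be (n, input_dim) with input_dim >= 3")
        y = np.asarray(list(y))
        self.classes_ = np.unique(y)
        binary = len(self.classes_) == 2
        idx = {c: i for i, c in enumerate(self.classes_)}
        y_enc = np.array([idx[v] for v in y], dtype=float if binary else int)
        cw = None
        if self.class_weight == "balanced":
            w = class_weights(y)
            cw = np.array([w[c] for c in self.classes_])
        self.net_ = PooledHeadNet(input_dim=V.shape[1], n_filters=self.n_filters,
                                  filter_width=self.filter_width, dense_units=self.dense_units,
                                  n_outputs=1 if binary else len(self.classes_), seed=self.seed)
        if validation is None:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(y_enc))
            n_val = max(1, int(round(self.validation_fraction * len(y_enc))))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            train = (V[tr_idx], y_enc[tr_idx])
            val = (V[val_idx], y_enc[val_idx])
        else:
            Vv, yv = validation
            yv_enc = np.array([idx[v] for v in yv], dtype=float if binary else int)
            train, val = (V, y_enc), (np.asarray(Vv, dtype=float), yv_enc)
        cfg = TrainConfig(lr=self.lr, epochs=self.epochs, batch_size=self.batch_size,
                          patience=self.patience, seed=self.seed,
                          loss="binary_ce" if binary else "categorical_ce_weighted",
                          class_weight=cw)
        self.history_ = fit_network(self.net_, train, val, cfg)
        self.n_outputs_ = 1 if binary else len(self.classes_)
        return self

    def decision_function(self, V):
        check_is_fitted(self, "net_")
        out, _ = self.net_.forward(np.asarray(V, dtype=float))
        return out[:, 0] if self.n_outputs_ == 1 else out

    def predict_proba(self, V):
        margins = self.decision_function(V)
        if self.n_outputs_ == 1:
            p = 1.0 / (1.0 + np.exp(-margins))
            return np.column_stack([1 - p, p])
        z = margins - margins.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, V):
        return self.classes_[np.argmax(self.predict_proba(V), axis=1)]


def build_pooled_head(input_dim: int, task: str = "ltr_detection", seed: int = 0, **kwargs) -> ModelHandle:
    if input_dim < 3:
        raise ValueError("input_dim must be >= 3")
    clf = PooledHeadClassifier(task=task, seed=seed, **kwargs)
    return ModelHandle(kind="pooled_head", task=task, model=clf, seed=seed,
                       hyperparams=clf.get_params(), fitted=False)


class PooledEmbeddingClassifier(BaseEstimator, ClassifierMixin):
    """Windowed embedder + average pooling + convolutional head, end to end."""

    def __init__(self, embedder=None, window: int = 510, stride: int = 170,
                 head_params: dict | None = None, seed: int = 0):
        self.embedder = embedder
        self.window = window
        self.stride = stride
        self.head_params = head_params
        self.seed = seed

    def _embed(self, X) -> np.ndarray:
        embedder = self.embedder or KmerHashEmbedder(seed=self.seed)
        return np.stack([
            window_pool_embeddings(s, embedder, window=self.window, stride=self.stride) for s in X
        ])

    def fit(self, X, y, validation=None):
        V = self._embed(X)
        self.head_ = PooledHeadClassifier(seed=self.seed, **(self.head_params or {}))
        if validation is not None:
            Xv, yv = validation
            validation = (self._embed(Xv), yv)
        self.head_.fit(V, y, validation=validation)
        self.classes_ = self.head_.classes_
        self.history_ = self.head_.history_
        return self

    def predict(self, X):
        return self.head_.predict(self._embed(X))

    def predict_proba(self, X):
        return self.head_.predict_proba(self._embed(X))

    def decision_function(self, X):
        return self.head_.decision_function(self._embed(X))
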
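"""Minimal numpy neural-network engine for the sequence models.

Implements exactly the two topologies the toolkit trains -- the
Conv1D -> MaxPool -> LSTM -> Dense sequence classifier and the small
convolutional head over pooled embedding vectors -- with Adam, masked
recurrence over zero-padded batches, full backpropagation (including
gradients with respect to the input, used by the attribution layer), and
early stopping with best-weight restoration.

Shapes: one-hot batches are (B, L, C) with C=4 channel order A,C,G,T;
masks are (B, L) booleans marking real (un-padded) positions.  Padding is
always terminal (3' end), and masked steps carry the LSTM state through
unchanged, so the final hidden state equals the state at the last real
position.  All randomness flows through seeded numpy Generators; training
is reproducible for a fixed seed and BLAS configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

_NEG = -1e9  # sentinel for masked positions entering a max-pool


class TrainingError(RuntimeError):
    pass


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Adam:
    """Adam optimizer over a dict of parameter arrays (updates in place)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CnnLstmNet:
    """Conv1D (valid) -> max pool -> masked LSTM -> dense output.

    ``n_outputs`` is 1 for the binary tasks (sigmoid applied by the loss)
    and the class count for the softmax family task.  First-layer filters
    are exposed via :meth:`filter_matrices` as (filter_width, 4) position
    weight matrices.
    """

    def __init__(self, n_filters: int = 64, filter_width: int = 12, pool_size: int = 4,
                 lstm_units: int = 64, n_outputs: int = 1, in_channels: int = 4, seed: int = 0,
                 forget_bias: float = 1.0):
        self.n_filters, self.filter_width = n_filters, filter_width
        self.pool_size, self.lstm_units = pool_size, lstm_units
        self.n_outputs, self.in_channels = n_outputs, in_channels
        self.forget_bias = forget_bias
        rng = np.random.default_rng(seed)
        F, W, H, C, O = n_filters, filter_width, lstm_units, in_channels, n_outputs
        self.params = {
            "Wc": _glorot(rng, C * W, F, (C * W, F)),
            "bc": np.zeros(F),
            "Wx": _glorot(rng, F, 4 * H, (F, 4 * H)),
            "Wh": _glorot(rng, H, 4 * H, (H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wo": _glorot(rng, H, O, (H, O)),
            "bo": np.zeros(O),
        }
        # positive forget-gate bias lengthens the initial memory horizon
        self.params["b"][H : 2 * H] = forget_bias

    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def filter_matrices(self) -> list[np.ndarray]:
        """First-layer filters as (filter_width, in_channels) matrices."""
        Wc = self.params["Wc"].reshape(self.in_channels, self.filter_width, self.n_filters)
        return [Wc[:, :, f].T.copy() for f in range(self.n_filters)]

    def forward(self, X: np.ndarray, mask: np.ndarray, need_cache: bool = False):
        """Margins (pre-sigmoid/softmax) of shape (B, n_outputs)."""
        p = self.params
        X = np.asarray(X, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        B, L, C = X.shape
        W, F, H, P = self.filter_width, self.n_filters, self.lstm_units, self.pool_size
        if L < W:  # degenerate: pad up to one conv window
            X = np.concatenate([X, np.zeros((B, W - L, C))], axis=1)
            mask = np.concatenate([mask, np.zeros((B, W - L), dtype=bool)], axis=1)
            L = W
        Lc = L - W + 1
        lengths = mask.sum(axis=1)
        lc = np.maximum(lengths - W + 1, 0)  # conv window real iff fully inside real bases
        mask_c = np.arange(Lc)[None, :] < lc[:, None]
        Xcol = np.lib.stride_tricks.sliding_window_view(X, W, axis=1).reshape(B, Lc, C * W)
        Z = Xcol @ p["Wc"] + p["bc"]
        A = np.maximum(Z, 0.0)
        Apool = np.where(mask_c[:, :, None], A, _NEG)
        Lp = -(-Lc // P)
        pad_p = Lp * P - Lc
        mask_cp = mask_c
        if pad_p:
            Apool = np.concatenate([Apool, np.full((B, pad_p, F), _NEG)], axis=1)
            mask_cp = np.concatenate([mask_c, np.zeros((B, pad_p), dtype=bool)], axis=1)
        Ar = Apool.reshape(B, Lp, P, F)
        amax = Ar.argmax(axis=2)
        pooled = np.take_along_axis(Ar, amax[:, :, None, :], axis=2)[:, :, 0, :]
        mask_p = mask_cp.reshape(B, Lp, P).any(axis=2)
        Pin = np.where(mask_p[:, :, None], pooled, 0.0)

        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(Lp):
            zt = Pin[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(zt[:, :H])
            f = _sigmoid(zt[:, H : 2 * H])
            g = np.tanh(zt[:, 2 * H : 3 * H])
            o = _sigmoid(zt[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            m = mask_p[:, t : t + 1].astype(float)
            if need_cache:
                steps.append((h, c, i, f, g, o, c_new, tanh_c, m))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
        out = h @ p["Wo"] + p["bo"]
        if not need_cache:
            return out, None
        cache = dict(Xcol=Xcol, Z=Z, mask_c=mask_c, pad_p=pad_p, amax=amax,
                     mask_p=mask_p, Pin=Pin, steps=steps, h_final=h,
                     B=B, L=L, C=C, Lc=Lc, Lp=Lp)
        return out, cache

    def backward(self, cache: dict, dout: np.ndarray, need_dX: bool = False):
        """Parameter gradients (and optionally d loss / d input one-hot)."""
        p = self.params
        B, Lc, Lp, C, L = cache["B"], cache["Lc"], cache["Lp"], cache["C"], cache["L"]
        W, F, H, P = self.filter_width, self.n_filters, self.lstm_units, self.pool_size
        grads = {
            "Wo": cache["h_final"].T @ dout,
            "bo": dout.sum(axis=0),
            "Wx": np.zeros_like(p["Wx"]),
            "Wh": np.zeros_like(p["Wh"]),
            "b": np.zeros_like(p["b"]),
        }
        dh = dout @ p["Wo"].T
        dc = np.zeros((B, H))
        dPin = np.zeros_like(cache["Pin"])
        for t in range(Lp - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tanh_c, m = cache["steps"][t]
            dh_new = dh * m
            dh_carry = dh * (1 - m)
            dc_new = dc * m
            dc_carry = dc * (1 - m)
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1 - tanh_c**2)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            grads["Wx"] += cache["Pin"][:, t].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dPin[:, t] = dz @ p["Wx"].T
            dh = dz @ p["Wh"].T + dh_carry
            dc = dc_new * f + dc_carry
        # pool backward: route gradient to the argmax conv position
        dpooled = dPin * cache["mask_p"][:, :, None]
        dAr = np.zeros((B, Lp, P, F))
        np.put_along_axis(dAr, cache["amax"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        dA = dAr.reshape(B, Lp * P, F)[:, :Lc, :]
        dZ = dA * (cache["Z"] > 0) * cache["mask_c"][:, :, None]
        grads["Wc"] = cache["Xcol"].reshape(B * Lc, C * W).T @ dZ.reshape(B * Lc, F)
        grads["bc"] = dZ.sum(axis=(0, 1))
        if not need_dX:
            return grads, None
        dXcol = (dZ @ p["Wc"].T).reshape(B, Lc, C, W)
        dX = np.zeros((B, L, C))
        for j in range(W):
            dX[:, j : j + Lc, :] += dXcol[:, :, :, j]
        return grads, dX

    def input_gradient(self, X: np.ndarray, mask: np.ndarray, output_index: int = 0) -> np.ndarray:
        """d margin[:, output_index] / d X, one batch forward+backward."""
        out, cache = self.forward(X, mask, need_cache=True)
        dout = np.zeros_like(out)
        dout[:, output_index] = 1.0
        _, dX = self.backward(cache, dout, need_dX=True)
        return dX


class PooledHeadNet:
    """Conv (32 filters of width 3) over a pooled embedding vector,
    global max pool, dense 32, task output."""

    def __init__(self, input_dim: int, n_filters: int = 32, filter_width: int = 3,
                 dense_units: int = 32, n_outputs: int = 1, seed: int = 0):
        if input_dim < filter_width:
            raise ValueError("input_dim must be >= filter_width")
        self.input_dim, self.n_filters = input_dim, n_filters
        self.filter_width, self.dense_units, self.n_outputs = filter_width, dense_units, n_outputs
        rng = np.random.default_rng(seed)
        Wd, F, D, O = filter_width, n_filters, dense_units, n_outputs
        self.params = {
            "Wc": _glorot(rng, Wd, F, (Wd, F)),
            "bc": np.zeros(F),
            "W1": _glorot(rng, F, D, (F, D)),
            "b1": np.zeros(D),
            "Wo": _glorot(rng, D, O, (D, O)),
            "bo": np.zeros(O),
        }

    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def forward(self, V: np.ndarray, need_cache: bool = False):
        p = self.params
        V = np.asarray(V, dtype=float)
        B, D = V.shape
        Wd, F = self.filter_width, self.n_filters
        Vcol = np.lib.stride_tricks.sliding_window_view(V, Wd, axis=1)  # (B, D-Wd+1, Wd)
        Z = Vcol @ p["Wc"] + p["bc"]
        A = np.maximum(Z, 0.0)
        amax = A.argmax(axis=1)  # (B, F)
        pooled = np.take_along_axis(A, amax[:, None, :], axis=1)[:, 0, :]
        Z1 = pooled @ p["W1"] + p["b1"]
        A1 = np.maximum(Z1, 0.0)
        out = A1 @ p["Wo"] + p["bo"]
        if not need_cache:
            return out, None
        return out, dict(Vcol=Vcol, Z=Z, amax=amax, pooled=pooled, Z1=Z1, A1=A1, B=B, D=D)

    def backward(self, cache: dict, dout: np.ndarray):
        p = self.params
        B, D = cache["B"], cache["D"]
        Wd, F = self.filter_width, self.n_filters
        grads = {"Wo": cache["A1"].T @ dout, "bo": dout.sum(axis=0)}
        dA1 = dout @ p["Wo"].T
        dZ1 = dA1 * (cache["Z1"] > 0)
        grads["W1"] = cache["pooled"].T @ dZ1
        grads["b1"] = dZ1.sum(axis=0)
        dpooled = dZ1 @ p["W1"].T
        dA = np.zeros((B, D - Wd + 1, F))
        np.put_along_axis(dA, cache["amax"][:, None, :], dpooled[:, None, :], axis=1)
        dZ = dA * (cache["Z"] > 0)
        grads["Wc"] = np.einsum("btw,btf->wf", cache["Vcol"], dZ)
        grads["bc"] = dZ.sum(axis=(0, 1))
        return grads, None


# ---------------------------------------------------------------------------
# losses and the training loop


def binary_ce(margins: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None):
    """Sigmoid + binary cross entropy; returns (loss, d loss/d margins)."""
    z = margins[:, 0]
    p = _sigmoid(z)
    w = np.ones_like(z) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    eps = 1e-12
    loss = float(np.mean(-w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))
    dm = (w * (p - y) / len(z))[:, None]
    return loss, dm


def softmax_ce(margins: np.ndarray, y: np.ndarray, class_weight: np.ndarray | None = None):
    """Softmax + (class-weighted) categorical cross entropy."""
    z = margins - margins.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n, K = margins.shape
    w = np.ones(n) if class_weight is None else np.asarray(class_weight, dtype=float)[y]
    eps = 1e-12
    loss = float(np.mean(-w * np.log(probs[np.arange(n), y] + eps)))
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0
    dm = w[:, None] * (probs - onehot) / n
    return loss, dm


@dataclass
class TrainConfig:
    """Training regime shared by the sequence models.

    Defaults mirror the regime used throughout: Adam, 15 epochs, batches
    of 64, early stopping with a 3-epoch patience on the validation loss
    (best weights restored).
    """

    optimizer: str = "adam"
    lr: float = 1e-3
    epochs: int = 15
    batch_size: int = 64
    patience: int = 3
    loss: str = "binary_ce"  # binary_ce | categorical_ce_weighted
    seed: int = 0
    class_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience >= self.epochs:
            raise ValueError("patience must be smaller than epochs")
        if self.loss not in ("binary_ce", "categorical_ce_weighted", "bce_logits"):
            raise ValueError(f"unknown loss {self.loss!r}")


def _loss_fn(cfg: TrainConfig):
    if cfg.loss in ("binary_ce", "bce_logits"):
        cw = cfg.class_weight

        def fn(margins, y):
            sw = None if cw is None else np.asarray(cw)[y.astype(int)]
            return binary_ce(margins, y, sample_weight=sw)

        return fn
    return lambda margins, y: softmax_ce(margins, y, class_weight=cfg.class_weight)


def fit_network(net, train_batch, val_batch, cfg: TrainConfig) -> dict:
    """Mini-batch training with early stopping; returns the history.

    ``train_batch`` / ``val_batch`` are tuples ``(inputs..., y)`` where
    ``inputs`` is either ``(X, mask)`` for sequence nets or ``(V,)`` for
    the pooled head.  Early stopping restores the best-validation weights.
    """
    *train_inputs, y_train = train_batch
    *val_inputs, y_val = val_batch
    loss_fn = _loss_fn(cfg)
    opt = Adam(net.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    n = len(y_train)
    history = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_loss, best_params, since_best = np.inf, None, 0

    def eval_loss(inputs, y):
        total, count = 0.0, 0
        for sl in _batches(len(y), max(cfg.batch_size, 256)):
            out, _ = net.forward(*(a[sl] for a in inputs))
            loss, _ = loss_fn(out, y[sl])
            total += loss * (sl.stop - sl.start)
            count += sl.stop - sl.start
        return total / count

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        running = 0.0
        for sl in _batches(n, cfg.batch_size):
            idx = order[sl]
            out, cache = net.forward(*(a[idx] for a in train_inputs), need_cache=True)
            loss, dout = loss_fn(out, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            grads, _ = net.backward(cache, dout)
            opt.step(grads)
            running += loss * len(idx)
        history["train_loss"].append(running / n)
        val_loss = eval_loss(val_inputs, y_val)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = copy.deepcopy(net.params)
            history["best_epoch"] = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_params is not None:
        net.params.update(best_params)
        if hasattr(opt, "params"):
            opt.params = net.params
    return history


def _batches(n: int, size: int):
    for start in range(0, n, size):
        yield slice(start, min(start + size, n))
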
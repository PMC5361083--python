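"""A compact numpy engine for small sequence classifiers.

Implements exactly the two architectures the pipeline trains on encoded
posts, with explicit forward/backward passes:

* feed-forward: embedding -> flatten -> dropout -> dense(ReLU) -> softmax
* convolutional: embedding -> 1-D conv(ReLU) -> max-pool -> flatten ->
  dropout -> dense(ReLU) -> softmax

plus categorical cross-entropy, inverted dropout, Glorot/uniform
initialisation and an Adam optimiser. Everything is seeded through a
``numpy.random.Generator`` so training is reproducible bit-for-bit on a
given platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = np.finfo(probs.dtype).tiny
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


class Adam:
    """Adam with the customary decay rates (0.9 / 0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)


class _SequenceNet:
    """Common plumbing: embedding table, dropout, output layer, Adam-ready params."""

    def __init__(self, n_symbols: int, seq_len: int, n_classes: int,
                 embedding_dim: int, dropout: float, seed: int,
                 dtype=np.float32) -> None:
        self.n_symbols = n_symbols
        self.seq_len = seq_len
        self.n_classes = n_classes
        self.embedding_dim = embedding_dim
        self.dropout = dropout
        self.dtype = dtype
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {
            "E": self.rng.uniform(-0.05, 0.05, size=(n_symbols, embedding_dim)).astype(dtype)
        }

    def _dropout_mask(self, shape: tuple[int, ...], train: bool) -> np.ndarray | None:
        if not train or self.dropout <= 0.0:
            return None
        keep = 1.0 - self.dropout
        return (self.rng.random(shape) < keep).astype(self.dtype) / keep

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = np.empty((len(x), self.n_classes), dtype=self.dtype)
        for lo in range(0, len(x), batch_size):
            out[lo: lo + batch_size] = self._forward(x[lo: lo + batch_size], train=False)[0]
        return out

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


class FeedForwardNet(_SequenceNet):
    """embedding(d) -> flatten -> dropout -> dense(h, ReLU) -> softmax(K)."""

    def __init__(self, n_symbols: int, seq_len: int, n_classes: int,
                 embedding_dim: int = 16, dense_units: int = 64,
                 dropout: float = 0.25, seed: int = 0, dtype=np.float32) -> None:
        super().__init__(n_symbols, seq_len, n_classes, embedding_dim, dropout, seed, dtype)
        flat = seq_len * embedding_dim
        p, rng = self.params, self.rng
        p["W1"] = _glorot(rng, flat, dense_units, dtype)
        p["b1"] = np.zeros(dense_units, dtype=dtype)
        p["W2"] = _glorot(rng, dense_units, n_classes, dtype)
        p["b2"] = np.zeros(n_classes, dtype=dtype)

    def _forward(self, x: np.ndarray, train: bool):
        p = self.params
        H = p["E"][x]                                   # (B, L, d)
        flat = H.reshape(len(x), -1)
        mask = self._dropout_mask(flat.shape, train)
        fd = flat * mask if mask is not None else flat
        z1 = fd @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        probs = softmax(a1 @ p["W2"] + p["b2"])
        return probs, (x, flat, mask, fd, z1, a1)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True):
        p = self.params
        probs, (x, flat, mask, fd, z1, a1) = self._forward(x, train)
        loss = cross_entropy(probs, y)
        B = len(x)
        dz2 = probs.astype(self.dtype).copy()
        dz2[np.arange(B), y] -= 1.0
        dz2 /= B
        grads = {
            "W2": a1.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        dz1 = (dz2 @ p["W2"].T) * (z1 > 0)
        grads["W1"] = fd.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ p["W1"].T
        if mask is not None:
            dflat = dflat * mask
        dH = dflat.reshape(B, self.seq_len, self.embedding_dim)
        dE = np.zeros_like(p["E"])
        np.add.at(dE, x.ravel(), dH.reshape(-1, self.embedding_dim))
        grads["E"] = dE
        return loss, grads


class ConvNet(_SequenceNet):
    """embedding(d) -> conv1d(f, ReLU) -> max-pool(m) -> flatten -> dropout
    -> dense(h, ReLU) -> softmax(K)."""

    def __init__(self, n_symbols: int, seq_len: int, n_classes: int,
                 embedding_dim: int = 16, n_filters: int = 64,
                 filter_len: int = 5, pool_len: int = 2,
                 dense_units: int = 256, dropout: float = 0.25,
                 seed: int = 0, dtype=np.float32) -> None:
        super().__init__(n_symbols, seq_len, n_classes, embedding_dim, dropout, seed, dtype)
        if seq_len < filter_len:
            raise ValueError("sequence shorter than the convolution filter")
        self.n_filters = n_filters
        self.filter_len = filter_len
        self.pool_len = pool_len
        self.conv_len = seq_len - filter_len + 1
        self.pooled_len = self.conv_len // pool_len
        if self.pooled_len < 1:
            raise ValueError("pooling eliminates the whole sequence")
        flat = self.pooled_len * n_filters
        p, rng = self.params, self.rng
        p["Wc"] = _glorot(rng, filter_len * embedding_dim, n_filters, dtype)
        p["bc"] = np.zeros(n_filters, dtype=dtype)
        p["W1"] = _glorot(rng, flat, dense_units, dtype)
        p["b1"] = np.zeros(dense_units, dtype=dtype)
        p["W2"] = _glorot(rng, dense_units, n_classes, dtype)
        p["b2"] = np.zeros(n_classes, dtype=dtype)

    def _windows(self, H: np.ndarray) -> np.ndarray:
        # (B, conv_len, f, d) -> (B, conv_len, f*d), window-position major.
        win = sliding_window_view(H, self.filter_len, axis=1)  # (B, Lc, d, f)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            H.shape[0], self.conv_len, self.filter_len * self.embedding_dim
        )

    def _forward(self, x: np.ndarray, train: bool):
        p = self.params
        B = len(x)
        H = p["E"][x]                                    # (B, L, d)
        win = self._windows(H)                           # (B, Lc, f*d)
        zc = win @ p["Wc"] + p["bc"]                     # (B, Lc, F)
        ac = np.maximum(zc, 0.0)
        usable = self.pooled_len * self.pool_len
        blocks = ac[:, :usable].reshape(B, self.pooled_len, self.pool_len, self.n_filters)
        amax = blocks.argmax(axis=2)
        pooled = np.take_along_axis(blocks, amax[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(B, -1)
        mask = self._dropout_mask(flat.shape, train)
        fd = flat * mask if mask is not None else flat
        z1 = fd @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        probs = softmax(a1 @ p["W2"] + p["b2"])
        return probs, (x, win, zc, amax, mask, fd, z1, a1)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True):
        p = self.params
        probs, (x, win, zc, amax, mask, fd, z1, a1) = self._forward(x, train)
        loss = cross_entropy(probs, y)
        B = len(x)
        dz2 = probs.astype(self.dtype).copy()
        dz2[np.arange(B), y] -= 1.0
        dz2 /= B
        grads = {"W2": a1.T @ dz2, "b2": dz2.sum(axis=0)}
        dz1 = (dz2 @ p["W2"].T) * (z1 > 0)
        grads["W1"] = fd.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ p["W1"].T
        if mask is not None:
            dflat = dflat * mask
        dpool = dflat.reshape(B, self.pooled_len, self.n_filters)
        usable = self.pooled_len * self.pool_len
        dblocks = np.zeros((B, self.pooled_len, self.pool_len, self.n_filters), dtype=self.dtype)
        np.put_along_axis(dblocks, amax[:, :, None, :], dpool[:, :, None, :], axis=2)
        dac = np.zeros((B, self.conv_len, self.n_filters), dtype=self.dtype)
        dac[:, :usable] = dblocks.reshape(B, usable, self.n_filters)
        dzc = dac * (zc > 0)
        grads["Wc"] = win.reshape(-1, win.shape[-1]).T @ dzc.reshape(-1, self.n_filters)
        grads["bc"] = dzc.sum(axis=(0, 1))
        dwin = (dzc @ p["Wc"].T).reshape(
            B, self.conv_len, self.filter_len, self.embedding_dim
        )
        dH = np.zeros((B, self.seq_len, self.embedding_dim), dtype=self.dtype)
        for off in range(self.filter_len):
            dH[:, off: off + self.conv_len] += dwin[:, :, off]
        dE = np.zeros_like(p["E"])
        np.add.at(dE, x.ravel(), dH.reshape(-1, self.embedding_dim))
        grads["E"] = dE
        return loss, grads
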
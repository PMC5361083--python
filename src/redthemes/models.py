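"""The four post classifiers: feed-forward NN, CNN, linear, SVM.

All four consume the same encoded posts. The neural models read the raw
integer sequences through a 16-dimensional embedding; the linear and SVM
baselines see a term-frequency bag-of-words over the same vocabulary built
from the same (truncated, padded) sequences, so no classifier gets extra
text the others lack. Training of the neural models minimises categorical
cross-entropy with Adam, stopping at 100 epochs or once the validation
loss has not improved for 5 consecutive epochs (best weights restored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .nn import Adam, ConvNet, FeedForwardNet, softmax

Kind = Literal["ff", "cnn", "linear", "svm"]

_DENSE_UNITS = {"ff": 64, "cnn": 256}


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training regime of one classifier."""

    kind: Kind
    n_classes: int = 2
    embedding_dim: int = 16
    conv_filter_len: int = 5
    pool_len: int = 2
    n_filters: int = 64
    dense_units: int | None = None
    dropout: float = 0.25
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 128
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ff", "cnn", "linear", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.dense_units is None:
            object.__setattr__(self, "dense_units", _DENSE_UNITS.get(self.kind))
        elif self.kind in _DENSE_UNITS and self.dense_units <= 0:
            raise ValueError("dense_units must be positive")


@dataclass
class TrainingLog:
    """Per-epoch record of the neural training run."""

    epochs_run: int = 0
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False
    optimizer: str = "adam(lr=1e-3)"
    batch_size: int = 128


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply and audit it."""

    spec: ClassifierSpec
    class_order: tuple[str, ...]
    backend: object
    n_symbols: int
    seq_len: int
    log: TrainingLog | None = None


def bag_of_words(sequences: np.ndarray, n_symbols: int) -> sp.csr_matrix:
    """Term-frequency counts of each non-padding integer in each sequence."""
    n, seq_len = sequences.shape
    rows = np.repeat(np.arange(n), seq_len)
    cols = sequences.ravel()
    keep = cols != 0
    mat = sp.coo_matrix(
        (np.ones(keep.sum(), dtype=np.float32), (rows[keep], cols[keep])),
        shape=(n, n_symbols),
    )
    return mat.tocsr()


def _validation_split(n: int, fraction: float, rng: np.random.Generator):
    n_val = max(1, int(round(fraction * n))) if fraction > 0 else 0
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


def _fit_net(net, X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> TrainingLog:
    rng = np.random.default_rng(spec.seed + 1)
    train_idx, val_idx = _validation_split(len(X), spec.validation_fraction, rng)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]
    opt = Adam(lr=spec.learning_rate)
    log = TrainingLog(optimizer=f"adam(lr={spec.learning_rate})", batch_size=spec.batch_size)
    best_loss = np.inf
    best_params = net.clone_params()
    since_best = 0
    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(Xtr))
        losses = []
        for lo in range(0, len(order), spec.batch_size):
            sel = order[lo: lo + spec.batch_size]
            loss, grads = net.loss_and_grads(Xtr[sel], ytr[sel], train=True)
            opt.step(net.params, grads)
            losses.append(loss)
        log.train_loss.append(float(np.mean(losses)))
        if len(Xval):
            probs = net.predict_proba(Xval)
            eps = np.finfo(probs.dtype).tiny
            vloss = float(-np.log(probs[np.arange(len(yval)), yval] + eps).mean())
        else:
            vloss = log.train_loss[-1]
        log.val_loss.append(vloss)
        log.epochs_run = epoch + 1
        if vloss < best_loss:
            best_loss = vloss
            best_params = net.clone_params()
            log.best_epoch = epoch + 1
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.patience:
                log.stopped_early = True
                break
    net.set_params(best_params)
    return log


def train(
    spec: ClassifierSpec,
    sequences: np.ndarray,
    labels: Sequence[str],
    class_order: Sequence[str],
    n_symbols: int | None = None,
) -> TrainedModel:
    """Fit one classifier on encoded training posts.

    ``class_order`` fixes the column order of every probability the model
    will ever emit; all its classes must be present in the training labels.
    ``n_symbols`` is the number of distinct sequence integers (pad..oov,
    i.e. ``Vocabulary.n_symbols``); inferred from the data when omitted.
    """
    class_order = tuple(class_order)
    if spec.n_classes != len(class_order):
        raise ValueError("spec.n_classes does not match class_order")
    lookup = {c: i for i, c in enumerate(class_order)}
    missing = set(class_order) - set(labels)
    if missing:
        raise ValueError(f"classes absent from training labels: {sorted(missing)}")
    unknown = set(labels) - set(class_order)
    if unknown:
        raise ValueError(f"labels outside class_order: {sorted(unknown)}")
    X = np.asarray(sequences, dtype=np.int32)
    y = np.array([lookup[l] for l in labels], dtype=np.int64)
    if n_symbols is None:
        n_symbols = int(X.max()) + 1
    elif X.max() >= n_symbols:
        raise ValueError("sequences contain integers outside 0..n_symbols-1")
    seq_len = X.shape[1]

    if spec.kind == "ff":
        net = FeedForwardNet(
            n_symbols, seq_len, spec.n_classes,
            embedding_dim=spec.embedding_dim, dense_units=spec.dense_units,
            dropout=spec.dropout, seed=spec.seed,
        )
        log = _fit_net(net, X, y, spec)
        return TrainedModel(spec, class_order, net, n_symbols, seq_len, log)
    if spec.kind == "cnn":
        net = ConvNet(
            n_symbols, seq_len, spec.n_classes,
            embedding_dim=spec.embedding_dim, n_filters=spec.n_filters,
            filter_len=spec.conv_filter_len, pool_len=spec.pool_len,
            dense_units=spec.dense_units, dropout=spec.dropout, seed=spec.seed,
        )
        log = _fit_net(net, X, y, spec)
        return TrainedModel(spec, class_order, net, n_symbols, seq_len, log)

    bow = bag_of_words(X, n_symbols)
    if spec.kind == "linear":
        clf = LogisticRegression(max_iter=1000, random_state=spec.seed)
    else:
        clf = LinearSVC(random_state=spec.seed, max_iter=5000)
    clf.fit(bow, y)
    return TrainedModel(spec, class_order, clf, n_symbols, seq_len, None)


def predict_proba(model: TrainedModel, sequences: np.ndarray) -> np.ndarray:
    """Per-post probability vectors over ``model.class_order``.

    For the SVM the decision values are mapped through a softmax: a
    monotone calibration that preserves the class ranking without claiming
    calibrated probabilities.
    """
    X = np.asarray(sequences, dtype=np.int32)
    if X.ndim != 2 or X.shape[1] != model.seq_len:
        raise ValueError(
            f"expected sequences of length {model.seq_len}, got shape {X.shape}"
        )
    if X.max() >= model.n_symbols:
        raise ValueError("sequence contains symbols unseen by this model's vocabulary")
    kind = model.spec.kind
    if kind in ("ff", "cnn"):
        probs = model.backend.predict_proba(X).astype(np.float64)
        return probs / probs.sum(axis=1, keepdims=True)
    bow = bag_of_words(X, model.n_symbols)
    if kind == "linear":
        return model.backend.predict_proba(bow)
    scores = model.backend.decision_function(bow)
    if scores.ndim == 1:  # binary LinearSVC emits one margin
        scores = np.column_stack([-scores, scores])
    return softmax(scores.astype(np.float64))


def predict(model: TrainedModel, sequences: np.ndarray) -> list[str]:
    """Argmax class labels (first class wins probability ties)."""
    probs = predict_proba(model, sequences)
    return [model.class_order[i] for i in probs.argmax(axis=1)]


def save_model(model: TrainedModel, path) -> None:
    """Persist a fitted model (spec, class order, parameters, training log)."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> TrainedModel:
    import pickle

    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} does not contain a trained model")
    return model
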
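"""Small 1-D convolutional network for spectra, implemented in NumPy.

The classifier follows the compact design used for spectral fingerprints:
two convolution + max-pooling stages, a dense hidden layer and a softmax
output, trained with Adam on categorical cross-entropy under stratified
k-fold cross-validation.  Forward and backward passes are written directly
on NumPy arrays (im2col convolutions), which keeps the model fully
deterministic for a fixed seed and light enough for a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import StratifiedKFold

from .dataset import SpectraSet

__all__ = [
    "CnnArchitecture",
    "TrainConfig",
    "FoldResult",
    "stratified_kfold",
    "build_model",
    "train_cv",
    "train_single",
    "predict",
]


@dataclass(frozen=True)
class CnnArchitecture:
    """Two conv blocks (filters, kernel, pool), two dense layers.

    The default preset (16/32 filters, kernels 7/5, pool 4, dense 32) is this
    package's own choice, sized for desk-scale CPU training; every field is
    configurable.
    """

    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 7, 4), (32, 5, 4))
    dense_units: int = 32
    n_classes: int = 3
    input_length: int = 3601
    activation: str = "relu"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 2:
            raise ValueError("preset expects exactly two conv+pool blocks")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only the rectifier activation is implemented")

    def feature_lengths(self) -> list[int]:
        """Sequence length after each conv and pool stage; errors on underflow."""
        length = self.input_length
        out = []
        for filters, kernel, pool in self.conv_blocks:
            length = length - kernel + 1
            if length < 1:
                raise ValueError("kernel larger than remaining sequence length")
            length = length // pool
            if length < 1:
                raise ValueError("pooling reduces sequence length below 1")
            out.append(length)
        return out


@dataclass(frozen=True)
class TrainConfig:
    n_folds: int = 10
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    early_stop_patience: int = 10

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class FoldResult:
    fold_index: int
    train_loss_curve: list[float]
    val_loss_curve: list[float]
    val_accuracy: float
    model_ref: "CnnModel"


def stratified_kfold(labels, n_folds: int, seed: int = 0) -> np.ndarray:
    """Fold index per sample; per-class fold counts differ by at most 1."""
    labels = np.asarray([str(l) for l in labels])
    counts = {c: int(np.sum(labels == c)) for c in set(labels)}
    small = [c for c, n in counts.items() if n < n_folds]
    if small:
        raise ValueError(f"classes smaller than n_folds: {small}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = fold
    return fold_of


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv1D:
    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.w = rng.normal(0.0, scale, size=(in_channels * kernel, filters))
        self.b = np.zeros(filters)
        self.kernel = kernel
        self.in_channels = in_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, C, L) -> (B, F, L-k+1)
        cols = sliding_window_view(x, self.kernel, axis=2)  # (B, C, L', k)
        self._cols = cols.transpose(0, 2, 1, 3).reshape(x.shape[0], -1, self.w.shape[0])
        self._in_len = x.shape[2]
        out = self._cols @ self.w + self.b
        return out.transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout.transpose(0, 2, 1)  # (B, L', F)
        b, lp, f = d.shape
        flat_cols = self._cols.reshape(-1, self.w.shape[0])
        self.dw = flat_cols.T @ d.reshape(-1, f)
        self.db = d.sum(axis=(0, 1))
        dcols = (d @ self.w.T).reshape(b, lp, self.in_channels, self.kernel)
        dx = np.zeros((b, self.in_channels, self._in_len))
        for i in range(self.kernel):
            dx[:, :, i : i + lp] += dcols[:, :, :, i].transpose(0, 2, 1)
        return dx

    def params(self):
        return [("w", self), ("b", self)]


class _MaxPool1D:
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        lp = l // self.pool
        x = x[:, :, : lp * self.pool]
        blocks = x.reshape(b, c, lp, self.pool)
        self._argmax = blocks.argmax(axis=3)
        self._shape = (b, c, l, lp)
        return blocks.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, l, lp = self._shape
        dx = np.zeros((b, c, lp, self.pool))
        bi, ci, li = np.indices((b, c, lp))
        dx[bi, ci, li, self._argmax] = dout
        full = np.zeros((b, c, l))
        full[:, :, : lp * self.pool] = dx.reshape(b, c, lp * self.pool)
        return full

    def params(self):
        return []


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [("w", self), ("b", self)]


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CnnModel:
    """Trained/trainable network plus its class encoding."""

    def __init__(self, arch: CnnArchitecture, seed: int, class_order: tuple[str, ...] | None = None):
        self.arch = arch
        self.seed = seed
        self.class_order = class_order or tuple(f"class{i}" for i in range(arch.n_classes))
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        arch.feature_lengths()  # validate shapes early
        layers: list = []
        in_ch = 1
        length = arch.input_length
        for filters, kernel, pool in arch.conv_blocks:
            layers.append(_Conv1D(in_ch, filters, kernel, rng))
            layers.append(_ReLU())
            layers.append(_MaxPool1D(pool))
            length = (length - kernel + 1) // pool
            in_ch = filters
        layers.append(_Flatten())
        layers.append(_Dense(in_ch * length, arch.dense_units, rng))
        layers.append(_ReLU())
        if arch.dropout > 0:
            layers.append(_Dropout(arch.dropout, self._dropout_rng))
        layers.append(_Dense(arch.dense_units, arch.n_classes, rng))
        self.layers = layers

    # -- plumbing -----------------------------------------------------------

    def _set_training(self, training: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                layer.training = training

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.arch.input_length:
            raise ValueError("input length mismatch")
        self._set_training(training)
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward_logits(np.asarray(x, dtype=float), training=False))

    def parameters(self):
        for layer in self.layers:
            for name, owner in layer.params():
                yield name, owner

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(owner, name).copy() for name, owner in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (name, owner), w in zip(self.parameters(), weights):
            setattr(owner, name, w.copy())


class _Adam:
    def __init__(self, model: CnnModel, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for n, o in model.parameters()]
        self.v = [np.zeros_like(getattr(o, n)) for n, o in model.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (name, owner) in enumerate(self.model.parameters()):
            g = getattr(owner, "d" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            setattr(owner, name, getattr(owner, name) - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))


def build_model(arch: CnnArchitecture, seed: int = 0, class_order: tuple[str, ...] | None = None) -> CnnModel:
    """Initialized model; identical seeds give identical initial weights."""
    return CnnModel(arch, seed=seed, class_order=class_order)


def _one_hot_idx(labels: np.ndarray, class_order: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    return np.asarray([index[str(l)] for l in labels], dtype=int)


def _epoch_loss(model: CnnModel, x: np.ndarray, y_idx: np.ndarray, batch: int = 256) -> float:
    total = 0.0
    for start in range(0, x.shape[0], batch):
        sl = slice(start, start + batch)
        probs = _softmax(model.forward_logits(x[sl], training=False))
        total += -np.sum(np.log(np.clip(probs[np.arange(len(y_idx[sl])), y_idx[sl]], 1e-12, None)))
    return float(total / x.shape[0])


def train_model(
    model: CnnModel,
    x_train: np.ndarray,
    labels_train: np.ndarray,
    x_val: np.ndarray | None,
    labels_val: np.ndarray | None,
    config: TrainConfig,
    shuffle_seed: int = 0,
) -> tuple[list[float], list[float]]:
    """Adam / cross-entropy training loop with early stopping on validation loss.

    Returns (train loss curve, validation loss curve); with no validation set
    the validation curve repeats the training loss and early stopping is off.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_idx = _one_hot_idx(np.asarray(labels_train), model.class_order)
    have_val = x_val is not None and labels_val is not None
    if have_val:
        x_val = np.asarray(x_val, dtype=float)
        yv_idx = _one_hot_idx(np.asarray(labels_val), model.class_order)
    optimizer = _Adam(model, lr=config.learning_rate)
    rng = np.random.default_rng(shuffle_seed)
    n = x_train.shape[0]
    k = model.arch.n_classes

    train_curve: list[float] = []
    val_curve: list[float] = []
    best_val = np.inf
    best_weights = model.get_weights()
    stall = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        running = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward_logits(x_train[idx], training=True)
            probs = _softmax(logits)
            picked = np.clip(probs[np.arange(len(idx)), y_idx[idx]], 1e-12, None)
            loss = -float(np.mean(np.log(picked)))
            if not np.isfinite(loss):
                raise FloatingPointError("divergent (non-finite) training loss")
            running += loss * len(idx)
            grad = probs.copy()
            grad[np.arange(len(idx)), y_idx[idx]] -= 1.0
            grad /= len(idx)
            dout = grad
            for layer in reversed(model.layers):
                dout = layer.backward(dout)
            optimizer.step()
        train_curve.append(running / n)
        if have_val:
            vloss = _epoch_loss(model, x_val, yv_idx)
            val_curve.append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_weights = model.get_weights()
                stall = 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    break
        else:
            val_curve.append(train_curve[-1])
    if have_val:
        model.set_weights(best_weights)
    return train_curve, val_curve


def train_cv(group_a: SpectraSet, arch: CnnArchitecture, config: TrainConfig) -> list[FoldResult]:
    """Stratified k-fold cross-validation on the training group.

    Each fold trains a freshly initialized model on the other k-1 folds and
    validates on the held-out fold; loss curves and validation accuracy are
    recorded per fold.
    """
    class_order = tuple(group_a.classes)
    if len(class_order) != arch.n_classes:
        raise ValueError("arch.n_classes does not match the label set")
    x = group_a.absorbance
    if x.shape[1] != arch.input_length:
        raise ValueError("arch.input_length does not match the spectra")
    fold_of = stratified_kfold(group_a.labels, config.n_folds, seed=config.seed)
    results: list[FoldResult] = []
    for fold in range(config.n_folds):
        val_mask = fold_of == fold
        model = build_model(arch, seed=config.seed * 1000 + fold, class_order=class_order)
        train_curve, val_curve = train_model(
            model,
            x[~val_mask],
            group_a.labels[~val_mask],
            x[val_mask],
            group_a.labels[val_mask],
            config,
            shuffle_seed=config.seed * 1000 + fold + 500,
        )
        pred, _ = predict(model, x[val_mask])
        accuracy = 100.0 * float(np.mean(pred == group_a.labels[val_mask]))
        results.append(
            FoldResult(
                fold_index=fold,
                train_loss_curve=train_curve,
                val_loss_curve=val_curve,
                val_accuracy=accuracy,
                model_ref=model,
            )
        )
    return results


def train_single(
    group_a: SpectraSet, arch: CnnArchitecture, config: TrainConfig, seed_offset: int = 0
) -> CnnModel:
    """Train one model on the whole group (no held-out fold, no early stop)."""
    class_order = tuple(group_a.classes)
    model = build_model(arch, seed=config.seed * 1000 + 77 + seed_offset, class_order=class_order)
    train_model(
        model,
        group_a.absorbance,
        group_a.labels,
        None,
        None,
        config,
        shuffle_seed=config.seed * 1000 + 177 + seed_offset,
    )
    return model


def predict(model: CnnModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (argmax probability) and the probability matrix; deterministic."""
    probs = model.predict_proba(x)
    labels = np.asarray([model.class_order[i] for i in probs.argmax(axis=1)], dtype=object)
    return labels, probs
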
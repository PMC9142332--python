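"""Classification heads for tumor-class prediction.

Two architectures are provided:

* ``pfv_mlp`` (default): a multilayer perceptron on the 256-length pattern
  frequency vector — input 256 → n hidden neurons → m class outputs with a
  soft-max.  This is the natural head for the corner-pattern feature, since
  the feature vector itself carries the shape information.
* ``alexnet3d``: a small AlexNet-style volumetric network with 5 convolution
  layers (3D kernels, max-pooling of window 2 after layers 1, 2 and 5) and
  3 fully connected layers — 8 weighted layers — ending in a soft-max.
  Filter counts are classical AlexNet proportions scaled down to phantom-
  sized volumes.

Both run on a self-contained NumPy backend (im2col 3D convolution, inverted
dropout, Adam, soft-max cross-entropy) so the whole train/predict path is
seeded and bit-reproducible.  Training honours a 90/10 train/validation
split and an early-stopping rule that halts when validation loss and
accuracy are both constant for a fixed number of consecutive epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ClassifierConfig",
    "LayerSpec",
    "ArchitectureSpec",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyper-parameters of the classification head.

    Defaults: 65 epochs, learning rate 0.001, dropout 0.20, batch size 128,
    validation split 0.1, early stopping after 4 epochs of constant
    validation loss and accuracy.
    """

    n_classes: int = 3
    head: str = "pfv_mlp"
    epochs: int = 65
    learning_rate: float = 0.001
    dropout: float = 0.20
    batch_size: int = 128
    validation_split: float = 0.1
    early_stop_patience: int = 4
    seed: int = 0
    hidden_units: int = 128          # pfv_mlp hidden width
    input_shape: tuple[int, int, int] = (24, 24, 24)  # alexnet3d volume shape

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if not 0 < self.learning_rate < 1:
            raise ValueError("learning_rate must be in (0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 < self.validation_split < 1:
            raise ValueError("validation_split must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.head not in ("pfv_mlp", "alexnet3d"):
            raise ValueError(f"head must be 'pfv_mlp' or 'alexnet3d', got {self.head!r}")
        if self.head == "alexnet3d" and any(s % 8 != 0 for s in self.input_shape):
            raise ValueError(
                "alexnet3d applies three window-2 poolings; every input "
                f"dimension must be divisible by 8, got {self.input_shape}"
            )


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor: kind plus its inspectable hyper-parameters."""

    kind: str  # conv3d | maxpool3d | relu | dropout | flatten | dense | softmax
    out_channels: int = 0
    kernel: int = 0
    pool_window: int = 0
    units: int = 0
    rate: float = 0.0


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer descriptors for one head."""

    head: str
    layers: tuple[LayerSpec, ...]
    input_width: int = 0                       # pfv_mlp
    input_shape: tuple[int, int, int] = (0, 0, 0)  # alexnet3d
    n_classes: int = 2

    @property
    def n_conv_layers(self) -> int:
        return sum(1 for l in self.layers if l.kind == "conv3d")

    @property
    def n_dense_layers(self) -> int:
        return sum(1 for l in self.layers if l.kind == "dense")

    @property
    def pool_windows(self) -> list[int]:
        return [l.pool_window for l in self.layers if l.kind == "maxpool3d"]

    @property
    def output_width(self) -> int:
        return [l for l in self.layers if l.kind == "dense"][-1].units


def build_model(cfg: ClassifierConfig) -> ArchitectureSpec:
    """Construct the layer plan for the configured head."""
    if cfg.head == "pfv_mlp":
        layers = (
            LayerSpec("dense", units=cfg.hidden_units),
            LayerSpec("relu"),
            LayerSpec("dropout", rate=cfg.dropout),
            LayerSpec("dense", units=cfg.n_classes),
            LayerSpec("softmax"),
        )
        return ArchitectureSpec(head="pfv_mlp", layers=layers,
                                input_width=256, n_classes=cfg.n_classes)
    # alexnet3d: 5 conv + 3 dense, pooling (window 2) after conv 1, 2 and 5
    layers = (
        LayerSpec("conv3d", out_channels=8, kernel=3),
        LayerSpec("relu"),
        LayerSpec("maxpool3d", pool_window=2),
        LayerSpec("conv3d", out_channels=16, kernel=3),
        LayerSpec("relu"),
        LayerSpec("maxpool3d", pool_window=2),
        LayerSpec("conv3d", out_channels=16, kernel=3),
        LayerSpec("relu"),
        LayerSpec("conv3d", out_channels=16, kernel=3),
        LayerSpec("relu"),
        LayerSpec("conv3d", out_channels=8, kernel=3),
        LayerSpec("relu"),
        LayerSpec("maxpool3d", pool_window=2),
        LayerSpec("flatten"),
        LayerSpec("dense", units=64),
        LayerSpec("relu"),
        LayerSpec("dropout", rate=cfg.dropout),
        LayerSpec("dense", units=32),
        LayerSpec("relu"),
        LayerSpec("dense", units=cfg.n_classes),
        LayerSpec("softmax"),
    )
    return ArchitectureSpec(head="alexnet3d", layers=layers,
                            input_shape=cfg.input_shape, n_classes=cfg.n_classes)


# ---------------------------------------------------------------------------
# NumPy backend


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))  # uniform fan (Glorot)
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _ReLU:
    params = grads = ()

    def forward(self, x, training):
        self._m = x > 0
        return x * self._m

    def backward(self, g):
        return g * self._m


class _Dropout:
    params = grads = ()

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self._rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._m = None
            return x
        self._m = (self._rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._m

    def backward(self, g):
        return g if self._m is None else g * self._m


class _Flatten:
    params = grads = ()

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class _Conv3D:
    """3×3×3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in, fan_out = c_in * k**3, c_out * k**3
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(c_out, c_in * k**3))
        self.b = np.zeros(c_out)
        self.k, self.c_in, self.c_out = k, c_in, c_out

    def forward(self, x, training):
        # x: (N, C, D, H, W), pad 1 per spatial axis
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp_shape = xp.shape
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        # win: (N, C, D, H, W, k, k, k) -> cols (N*D*H*W, C*k^3)
        n, c, d, h, w = x.shape
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, c * k**3)
        self._cols = cols
        out = cols @ self.W.T + self.b
        return out.reshape(n, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, g):
        n, co, d, h, w = g.shape
        k, p = self.k, self.k // 2
        gflat = g.transpose(0, 2, 3, 4, 1).reshape(-1, co)
        self.dW = gflat.T @ self._cols
        self.db = gflat.sum(axis=0)
        dcols = (gflat @ self.W).reshape(n, d, h, w, self.c_in, k, k, k)
        dxp = np.zeros(self._xp_shape)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    dxp[:, :, dz:dz + d, dy:dy + h, dx:dx + w] += \
                        dcols[:, :, :, :, :, dz, dy, dx].transpose(0, 4, 1, 2, 3)
        return dxp[:, :, p:p + d, p:p + h, p:p + w]

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _MaxPool3D:
    """Non-overlapping max pooling, window = stride = 2."""

    params = grads = ()

    def forward(self, x, training):
        n, c, d, h, w = x.shape
        r = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5, 7))
        up = np.repeat(np.repeat(np.repeat(out, 2, axis=2), 2, axis=3), 2, axis=4)
        self._mask = x == up
        # break ties: at most one winner per window
        return out

    def backward(self, g):
        up = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4)
        return up * self._mask


def _build_network(spec: ArchitectureSpec, cfg: ClassifierConfig,
                   rng: np.random.Generator) -> list:
    layers: list = []
    if spec.head == "pfv_mlp":
        width = spec.input_width
        for ls in spec.layers:
            if ls.kind == "dense":
                layers.append(_Dense(width, ls.units, rng))
                width = ls.units
            elif ls.kind == "relu":
                layers.append(_ReLU())
            elif ls.kind == "dropout":
                layers.append(_Dropout(ls.rate, rng))
        return layers
    # alexnet3d: track channels and spatial shape for the flatten width
    c = 1
    shape = list(spec.input_shape)
    width = 0
    for ls in spec.layers:
        if ls.kind == "conv3d":
            layers.append(_Conv3D(c, ls.out_channels, ls.kernel, rng))
            c = ls.out_channels
        elif ls.kind == "maxpool3d":
            layers.append(_MaxPool3D())
            shape = [s // 2 for s in shape]
        elif ls.kind == "relu":
            layers.append(_ReLU())
        elif ls.kind == "dropout":
            layers.append(_Dropout(ls.rate, rng))
        elif ls.kind == "flatten":
            layers.append(_Flatten())
            width = c * int(np.prod(shape))
        elif ls.kind == "dense":
            layers.append(_Dense(width, ls.units, rng))
            width = ls.units
    return layers


def _forward(layers, x, training):
    for layer in layers:
        x = layer.forward(x, training)
    return x


class _Adam:
    def __init__(self, layers, lr: float):
        self.layers, self.lr = layers, lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for l in layers for p in l.params]
        self.v = [np.zeros_like(p) for l in layers for p in l.params]

    def step(self):
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                mhat = self.m[i] / (1 - self.beta1**self.t)
                vhat = self.v[i] / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1


# ---------------------------------------------------------------------------
# Training surface


@dataclass
class TrainedModel:
    """A fitted head: architecture, weights, labels and the training log.

    For the pfv_mlp head the model also carries the per-component feature
    standardization (mean and scale) fitted on the training set; normalized
    pattern frequencies are tiny (~1/256), and standardizing them puts the
    inputs on the unit scale the weight initialization assumes.
    """

    architecture: ArchitectureSpec
    config: ClassifierConfig
    parameters: list
    class_labels: tuple
    training_log: list
    feature_mean: Optional[np.ndarray] = None
    feature_scale: Optional[np.ndarray] = None

    def _network(self):
        rng = np.random.default_rng(self.config.seed)
        layers = _build_network(self.architecture, self.config, rng)
        i = 0
        for layer in layers:
            for p in layer.params:
                p[...] = self.parameters[i]
                i += 1
        return layers


def _prepare_x(spec: ArchitectureSpec, xs: Sequence[np.ndarray]) -> np.ndarray:
    arrs = [np.asarray(x, dtype=np.float64) for x in xs]
    if spec.head == "pfv_mlp":
        for a in arrs:
            if a.shape != (spec.input_width,):
                raise ValueError(
                    f"feature shape mismatch: expected ({spec.input_width},), got {a.shape}"
                )
        return np.stack(arrs)
    for a in arrs:
        if a.shape != tuple(spec.input_shape):
            raise ValueError(
                f"volume shape mismatch: expected {tuple(spec.input_shape)}, got {a.shape}"
            )
    x = np.stack(arrs)[:, None]  # add channel axis
    return x / 255.0


def train(spec: ArchitectureSpec,
          dataset: Sequence[tuple[np.ndarray, object]],
          cfg: ClassifierConfig) -> TrainedModel:
    """Fit a head on (feature-or-volume, label) pairs.

    Deterministic given ``cfg.seed``.  The dataset is shuffled once and split
    90/10 into training and validation; training stops early when validation
    loss and accuracy are both constant for ``early_stop_patience``
    consecutive epochs.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    labels = sorted({lab for _, lab in dataset})
    if len(labels) > cfg.n_classes:
        raise ValueError(
            f"dataset has {len(labels)} labels but n_classes={cfg.n_classes}"
        )
    label_index = {lab: i for i, lab in enumerate(labels)}

    x = _prepare_x(spec, [f for f, _ in dataset])
    y = np.array([label_index[lab] for _, lab in dataset])

    feature_mean = feature_scale = None
    if spec.head == "pfv_mlp":
        # center per component, but scale by one pooled std so that the
        # relative variance structure of the pattern counts is preserved
        feature_mean = x.mean(axis=0)
        pooled = float(np.sqrt((x.std(axis=0) ** 2).mean()))
        feature_scale = np.full(x.shape[1], pooled if pooled > 1e-12 else 1.0)
        x = (x - feature_mean) / feature_scale

    rng = np.random.default_rng(cfg.seed)
    layers = _build_network(spec, cfg, rng)

    order = rng.permutation(len(y))
    n_val = int(round(cfg.validation_split * len(y)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:  # degenerate tiny dataset: train on everything
        tr_idx, val_idx = order, order[:0]

    opt = _Adam(layers, cfg.learning_rate)
    log: list[dict] = []
    prev = None
    constant_epochs = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(tr_idx))
        epoch_loss, epoch_hits = 0.0, 0
        for start in range(0, len(tr_idx), cfg.batch_size):
            idx = tr_idx[perm[start:start + cfg.batch_size]]
            logits = _forward(layers, x[idx], training=True)
            probs = _softmax(logits)
            yb = y[idx]
            epoch_loss -= float(np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum())
            epoch_hits += int((probs.argmax(axis=1) == yb).sum())
            g = probs.copy()
            g[np.arange(len(yb)), yb] -= 1.0
            g /= len(yb)
            for layer in reversed(layers):
                g = layer.backward(g)
            opt.step()
        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / len(tr_idx),
            "train_accuracy": epoch_hits / len(tr_idx),
        }
        # validation metrics drive early stopping; with no held-out samples
        # the training metrics stand in
        if len(val_idx):
            vlogits = _forward(layers, x[val_idx], training=False)
            vprobs = _softmax(vlogits)
            record["val_loss"] = -float(
                np.log(vprobs[np.arange(len(val_idx)), y[val_idx]] + 1e-12).mean()
            )
            record["val_accuracy"] = float(
                (vprobs.argmax(axis=1) == y[val_idx]).mean()
            )
            monitored = (record["val_loss"], record["val_accuracy"])
        else:
            monitored = (record["train_loss"], record["train_accuracy"])
        log.append(record)
        if prev is not None and all(abs(a - b) < 1e-7 for a, b in zip(monitored, prev)):
            constant_epochs += 1
            if constant_epochs >= cfg.early_stop_patience:
                record["early_stopped"] = True
                break
        else:
            constant_epochs = 0
        prev = monitored

    params = [p.copy() for layer in layers for p in layer.params]
    return TrainedModel(
        architecture=spec, config=cfg, parameters=params,
        class_labels=tuple(labels), training_log=log,
        feature_mean=feature_mean, feature_scale=feature_scale,
    )


def predict(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Class-probability vector for one feature vector or volume.

    Probabilities are non-negative and sum to 1; the argmax (into
    ``model.class_labels``) is the predicted label.
    """
    return predict_batch(model, [x])[0]


def predict_batch(model: TrainedModel, xs: Sequence[np.ndarray]) -> np.ndarray:
    """Class-probability matrix (n_samples × n_classes)."""
    batch = _prepare_x(model.architecture, list(xs))
    if model.feature_mean is not None:
        batch = (batch - model.feature_mean) / model.feature_scale
    layers = model._network()
    return _softmax(_forward(layers, batch, training=False))


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a single-file checkpoint: weights plus embedded config JSON."""
    meta = {
        "config": asdict(model.config),
        "class_labels": list(model.class_labels),
        "training_log": model.training_log,
    }
    extras = {}
    if model.feature_mean is not None:
        extras["feature_mean"] = model.feature_mean
        extras["feature_scale"] = model.feature_scale
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"param_{i}": p for i, p in enumerate(model.parameters)},
        **extras,
    )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        n_params = sum(1 for f in data.files if f.startswith("param_"))
        params = [data[f"param_{i}"] for i in range(n_params)]
        feature_mean = data["feature_mean"] if "feature_mean" in data.files else None
        feature_scale = data["feature_scale"] if "feature_scale" in data.files else None
    raw = meta["config"]
    raw["input_shape"] = tuple(raw["input_shape"])
    cfg = ClassifierConfig(**raw)
    return TrainedModel(
        architecture=build_model(cfg),
        config=cfg,
        parameters=params,
        class_labels=tuple(meta["class_labels"]),
        training_log=meta["training_log"],
        feature_mean=feature_mean,
        feature_scale=feature_scale,
    )
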
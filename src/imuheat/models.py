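"""Activity classifiers: raw-signal LSTM, 1-D ConvLSTM and image ConvLSTM.

Three architectures solve the same C-class problem from different views of a
recording window:

* ``lstm_raw`` — two stacked LSTM layers over the raw per-frame feature
  sequence, a fully connected interpretation layer, and a softmax output;
* ``convlstm_1d`` — the image architecture with 1-D kernels over the feature
  axis, consuming the raw sequence cut into sub-windows;
* ``convlstm_image`` — two ConvLSTM layers (16 filters of 5x5 then 32 of
  3x3), each followed by spatial 2x2 max-pooling, then time-distributed
  flattening and a dense interpretation layer, then softmax, consuming the
  (sub_windows, channels, H, W) heatmap tensors.

All are trained with Adam on the categorical cross-entropy

    L = -log( exp(s_p) / sum_j exp(s_j) )

with early stopping on validation loss and best-weight restoration. Training
is fully deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Adam, Tensor

__all__ = [
    "ModelConfig",
    "Prediction",
    "TrainLogEntry",
    "categorical_cross_entropy",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
    "save_training_log",
]

MODEL_KINDS = ("lstm_raw", "convlstm_1d", "convlstm_image")


@dataclass(frozen=True)
class ModelConfig:
    kind: str
    n_classes: int
    input_shape: tuple  # lstm_raw/convlstm_1d: (frames, features); image: (T, C, H, W)
    lstm_units: tuple[int, int] = (100, 100)
    conv_filters: tuple = ((16, 5), (32, 3))
    pool_size: int = 2
    dense_units: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    early_stopping_patience: int = 10
    early_stopping_min_delta: float = 0.0
    n_sub: int = 4  # sub-windows the 1-D ConvLSTM cuts the raw sequence into
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        shape = tuple(self.input_shape)
        object.__setattr__(self, "input_shape", shape)
        if self.kind in ("lstm_raw", "convlstm_1d") and len(shape) != 2:
            raise ValueError(f"{self.kind} expects input_shape (frames, features)")
        if self.kind == "convlstm_image" and len(shape) != 4:
            raise ValueError("convlstm_image expects input_shape (sub_windows, channels, H, W)")
        if self.kind == "convlstm_1d" and shape[0] % self.n_sub:
            raise ValueError("frames must be divisible by n_sub for convlstm_1d")


@dataclass(frozen=True)
class Prediction:
    s: np.ndarray  # pre-softmax scores, length C
    p: np.ndarray  # probabilities, length C
    predicted: int  # argmax class; ties break toward the lowest index


@dataclass(frozen=True)
class TrainLogEntry:
    epoch: int
    train_loss: float
    val_loss: float
    val_accuracy: float


def categorical_cross_entropy(s: np.ndarray, target_class: int) -> float:
    """Cross-entropy of one score vector: -log softmax(s)[target], evaluated
    stably via log-sum-exp."""
    s = np.asarray(s, float)
    if s.ndim != 1:
        raise ValueError("s must be a 1-D score vector")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if not 0 <= target_class < s.size:
        raise IndexError(f"target_class {target_class} out of range for {s.size} classes")
    m = s.max()
    return float(m + np.log(np.exp(s - m).sum()) - s[target_class])


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class _LSTMLayer:
    """Standard LSTM over a (N, T, D) sequence; gate order i, f, g, o with
    forget-gate bias initialized to 1."""

    def __init__(self, rng, d_in: int, units: int):
        self.units = units
        self.Wx = _glorot(rng, (d_in, 4 * units), d_in, units)
        self.Wh = _glorot(rng, (units, 4 * units), units, units)
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0
        self.b = Tensor(b, requires_grad=True)

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def __call__(self, x: Tensor, return_sequences: bool = False):
        n, T, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((n, u)))
        c = Tensor(np.zeros((n, u)))
        outs = []
        for t in range(T):
            xt = _nn.reshape(_nn.narrow(x, 1, t, 1), (n, -1))
            z = _nn.matmul(xt, self.Wx) + _nn.matmul(h, self.Wh) + self.b
            i = _nn.sigmoid(_nn.narrow(z, 1, 0, u))
            f = _nn.sigmoid(_nn.narrow(z, 1, u, u))
            g = _nn.tanh(_nn.narrow(z, 1, 2 * u, u))
            o = _nn.sigmoid(_nn.narrow(z, 1, 3 * u, u))
            c = f * c + i * g
            h = o * _nn.tanh(c)
            if return_sequences:
                outs.append(h)
        return _nn.stack(outs, axis=1) if return_sequences else h


class _ConvLSTMLayer:
    """Convolutional LSTM; state transitions are 'same'-padded convolutions.
    ``ndim`` selects 2D (images) or 1D (signals) kernels."""

    def __init__(self, rng, c_in: int, filters: int, kernel: int, ndim: int):
        self.filters = filters
        self.ndim = ndim
        k = (kernel,) * ndim
        fan_in = c_in * kernel**ndim
        fan_out = filters * kernel**ndim
        self.Wx = _glorot(rng, (4 * filters, c_in) + k, fan_in, fan_out)
        self.Wh = _glorot(rng, (4 * filters, filters) + k, filters * kernel**ndim, fan_out)
        b = np.zeros(4 * filters)
        b[filters : 2 * filters] = 1.0
        self.b = Tensor(b, requires_grad=True)
        self._conv = _nn.conv2d if ndim == 2 else _nn.conv1d

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def __call__(self, steps: list[Tensor]) -> list[Tensor]:
        f_ = self.filters
        n = steps[0].shape[0]
        spatial = steps[0].shape[2:]
        h = Tensor(np.zeros((n, f_) + spatial))
        c = Tensor(np.zeros((n, f_) + spatial))
        outs = []
        for xt in steps:
            z = self._conv(xt, self.Wx, self.b) + self._conv(h, self.Wh)
            i = _nn.sigmoid(_nn.narrow(z, 1, 0, f_))
            fg = _nn.sigmoid(_nn.narrow(z, 1, f_, f_))
            g = _nn.tanh(_nn.narrow(z, 1, 2 * f_, f_))
            o = _nn.sigmoid(_nn.narrow(z, 1, 3 * f_, f_))
            c = fg * c + i * g
            h = o * _nn.tanh(c)
            outs.append(h)
        return outs


class _Dense:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    @property
    def params(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return _nn.matmul(x, self.W) + self.b


class _BaseModel:
    config: ModelConfig
    layers: list

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.data = w.copy()

    def forward(self, X: np.ndarray) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class RawSignalLSTM(_BaseModel):
    """lstm_raw: LSTM -> LSTM -> dense interpretation layer -> softmax scores."""

    def __init__(self, cfg: ModelConfig):
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        frames, feats = cfg.input_shape
        u1, u2 = cfg.lstm_units
        self.lstm1 = _LSTMLayer(rng, feats, u1)
        self.lstm2 = _LSTMLayer(rng, u1, u2)
        self.dense = _Dense(rng, u2, cfg.dense_units)
        self.out = _Dense(rng, cfg.dense_units, cfg.n_classes)
        self.layers = [self.lstm1, self.lstm2, self.dense, self.out]

    def forward(self, X: np.ndarray) -> Tensor:
        x = Tensor(X)
        seq = self.lstm1(x, return_sequences=True)
        h = self.lstm2(seq, return_sequences=False)
        h = _nn.relu(self.dense(h))
        return self.out(h)


class _ConvLSTMClassifier(_BaseModel):
    """Shared topology of the 1-D and image ConvLSTM models: two ConvLSTM
    layers each followed by max-pooling, time-distributed flatten + dense,
    then a dense softmax head over the concatenated per-step features."""

    def __init__(self, cfg: ModelConfig, ndim: int, c_in: int, spatial: tuple):
        self.config = cfg
        self.ndim = ndim
        rng = np.random.default_rng(cfg.seed)
        (f1, k1), (f2, k2) = cfg.conv_filters
        self.conv1 = _ConvLSTMLayer(rng, c_in, f1, k1, ndim)
        self.conv2 = _ConvLSTMLayer(rng, f1, f2, k2, ndim)
        pooled = tuple(s // cfg.pool_size**2 for s in spatial)
        flat = f2 * int(np.prod(pooled))
        self.td_dense = _Dense(rng, flat, cfg.dense_units)
        T = cfg.input_shape[0] if ndim == 2 else cfg.n_sub
        self.out = _Dense(rng, T * cfg.dense_units, cfg.n_classes)
        self.layers = [self.conv1, self.conv2, self.td_dense, self.out]
        self._pool = _nn.maxpool2d if ndim == 2 else _nn.maxpool1d

    def _steps(self, X: np.ndarray) -> list[Tensor]:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, X: np.ndarray) -> Tensor:
        steps = self._steps(X)
        steps = [self._pool(h, self.config.pool_size) for h in self.conv1(steps)]
        steps = [self._pool(h, self.config.pool_size) for h in self.conv2(steps)]
        n = X.shape[0]
        feats = [_nn.relu(self.td_dense(_nn.reshape(h, (n, -1)))) for h in steps]
        return self.out(_nn.reshape(_nn.stack(feats, axis=1), (n, -1)))


class ImageConvLSTM(_ConvLSTMClassifier):
    """convlstm_image over (N, T, C, H, W) heatmap tensors."""

    def __init__(self, cfg: ModelConfig):
        T, C, H, W = cfg.input_shape
        super().__init__(cfg, ndim=2, c_in=C, spatial=(H, W))

    def _steps(self, X: np.ndarray) -> list[Tensor]:
        x = Tensor(X)
        T = self.config.input_shape[0]
        n = X.shape[0]
        return [
            _nn.reshape(_nn.narrow(x, 1, t, 1), (n,) + self.config.input_shape[1:])
            for t in range(T)
        ]


class ConvLSTM1D(_ConvLSTMClassifier):
    """convlstm_1d: the raw (frames, features) sequence cut into n_sub
    sub-windows; within each step, kernels slide over the feature axis and
    the frames of the sub-window act as channels."""

    def __init__(self, cfg: ModelConfig):
        frames, feats = cfg.input_shape
        super().__init__(cfg, ndim=1, c_in=frames // cfg.n_sub, spatial=(feats,))

    def _steps(self, X: np.ndarray) -> list[Tensor]:
        n, frames, feats = X.shape
        n_sub = self.config.n_sub
        x = Tensor(X)
        step_len = frames // n_sub
        return [
            _nn.reshape(_nn.narrow(x, 1, t * step_len, step_len), (n, step_len, feats))
            for t in range(n_sub)
        ]


def build_model(cfg: ModelConfig) -> _BaseModel:
    """Instantiate an untrained model with seeded parameter initialization."""
    if cfg.kind == "lstm_raw":
        return RawSignalLSTM(cfg)
    if cfg.kind == "convlstm_1d":
        return ConvLSTM1D(cfg)
    return ImageConvLSTM(cfg)


def _epoch_eval(model: _BaseModel, X: np.ndarray, y: np.ndarray, batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for a in range(0, len(X), batch):
        logits = model.forward(X[a : a + batch])
        loss = _nn.softmax_cross_entropy(logits, y[a : a + batch])
        losses.append(loss.data * (min(a + batch, len(X)) - a))
        correct += int(np.sum(np.argmax(logits.data, axis=1) == y[a : a + batch]))
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(
    model: _BaseModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    verbose: bool = False,
) -> list[TrainLogEntry]:
    """Adam + early stopping on validation loss; the best-validation weights
    are restored before returning. Returns the per-epoch training log."""
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    cfg = model.config
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=cfg.learning_rate)
    best_loss, best_weights, since_best = np.inf, model.get_weights(), 0
    log: list[TrainLogEntry] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_train))
        train_losses = []
        for a in range(0, len(order), cfg.batch_size):
            idx = order[a : a + cfg.batch_size]
            opt.zero_grad()
            loss = _nn.softmax_cross_entropy(model.forward(X_train[idx]), y_train[idx])
            loss.backward()
            opt.step()
            train_losses.append(loss.data * len(idx))
        train_loss = float(np.sum(train_losses) / len(order))
        val_loss, val_acc = _epoch_eval(model, X_val, y_val, cfg.batch_size)
        log.append(TrainLogEntry(epoch, train_loss, val_loss, val_acc))
        if verbose:  # pragma: no cover
            print(f"epoch {epoch}: train {train_loss:.4f} val {val_loss:.4f} acc {val_acc:.3f}")
        if val_loss < best_loss - cfg.early_stopping_min_delta:
            best_loss, best_weights, since_best = val_loss, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= max(1, cfg.early_stopping_patience):
                break
    model.set_weights(best_weights)
    return log


def save_model(model: _BaseModel, path) -> None:
    """Persist a model as an .npz of weight arrays plus its JSON-encoded
    config and a hash of that config for provenance checks on load."""
    import hashlib
    import json
    from dataclasses import asdict

    cfg_json = json.dumps(asdict(model.config), sort_keys=True, default=str)
    arrays = {f"w{k}": w for k, w in enumerate(model.get_weights())}
    np.savez(
        path,
        __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
        __config_hash__=np.frombuffer(
            hashlib.md5(cfg_json.encode()).hexdigest().encode(), dtype=np.uint8
        ),
        **arrays,
    )


def load_model(path) -> _BaseModel:
    import json

    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        cfg_dict["lstm_units"] = tuple(cfg_dict["lstm_units"])
        cfg_dict["conv_filters"] = tuple(tuple(f) for f in cfg_dict["conv_filters"])
        model = build_model(ModelConfig(**cfg_dict))
        n = len(model.params)
        model.set_weights([data[f"w{k}"] for k in range(n)])
    return model


def save_training_log(log: list[TrainLogEntry], path) -> None:
    """Write the per-epoch log as CSV (epoch, train_loss, val_loss, val_accuracy)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_loss", "val_accuracy"])
        for e in log:
            writer.writerow([e.epoch, repr(e.train_loss), repr(e.val_loss), repr(e.val_accuracy)])


def predict(model: _BaseModel, X: np.ndarray, batch: int = 32) -> list[Prediction]:
    """Score samples and return per-sample predictions; argmax ties break
    toward the lowest class index."""
    if X.shape[1:] != tuple(model.config.input_shape):
        raise ValueError(
            f"sample shape {X.shape[1:]} does not match model input {model.config.input_shape}"
        )
    preds: list[Prediction] = []
    for a in range(0, len(X), batch):
        logits = model.forward(X[a : a + batch]).data
        probs = _nn.softmax(logits)
        for s, p in zip(logits, probs):
            preds.append(Prediction(s=s, p=p, predicted=int(np.argmax(p))))
    return preds
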
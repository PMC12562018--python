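"""Classifier stacks for PD-vs-HC voice screening.

Four deep architectures operate on the (40 frames x 128 mel bands)
log-mel grid:

* ``bilstm``   — Conv2D(32, 3x3) > pool > Conv2D(64, 2x3) > pool >
  reshape to 40 timesteps > BiLSTM(64, sequences) > BiLSTM(32) >
  Dense(64, ReLU) + Dropout(0.5) > Dense(1, sigmoid)
* ``cnn_lstm`` — same CNN front end with 3x3/3x3 kernels, LSTM(64,
  sequences) > LSTM(32) recurrence
* ``cnn_gru``  — 2x3/3x3 kernels, GRU(64, sequences) > GRU(32)
* ``dnn``      — Flatten > Dense 256/128/64 (ReLU, dropout 0.5 on the
  first two) > Dense(1, sigmoid)

All deep models train with Adam (lr 0.001) on binary cross-entropy,
batch size 16, 80-20 stratified train/validation split, and are exactly
reproducible given ``random_state``.  The two pooling stages reduce the
grid to 10 x 32 x 64 = 20480 activations, reshaped to 40 timesteps of
512 features — the canonical reading of a flatten-then-reshape(40) step.

Classical baselines (RBF-kernel SVM, gradient-boosted trees via
XGBoost, L2 logistic regression) consume the acoustic feature vectors
and are tuned by stratified grid-search CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "DEEP_ARCHITECTURES",
    "CLASSICAL_KINDS",
    "build_model",
    "NeuralSequenceClassifier",
    "fit_classical",
]

DEEP_ARCHITECTURES = ("bilstm", "cnn_lstm", "cnn_gru", "dnn")
CLASSICAL_KINDS = ("svm", "xgboost", "logreg")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative layer stack for one architecture."""

    name: str
    layers: tuple[dict, ...]
    input_shape: tuple[int, int]

    def final_layer(self) -> dict:
        return self.layers[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Deep-model training regime (defaults follow the study setup)."""

    optimizer: str = "adam"
    learning_rate: float = 0.001
    loss: str = "binary_cross_entropy"
    epochs: int = 20
    batch_size: int = 16
    split: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.split < 1):
            raise ValueError("split must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


#: published per-architecture epoch defaults
DEFAULT_EPOCHS = {"cnn_lstm": 50, "bilstm": 20, "cnn_gru": 20, "dnn": 20}


def build_model(name: str, input_shape: tuple[int, int] = (40, 128)) -> ModelSpec:
    """Return the declarative stack for ``name``.

    The CNN front ends require the reshape-to-40-timesteps step to
    divide evenly: with a (40, 128) input two 2x2 poolings leave
    10 x 32 x 64 = 20480 values = 40 x 512.
    """
    name = name.lower()
    t, m = input_shape
    if name not in DEEP_ARCHITECTURES:
        raise ValueError(f"unknown architecture {name!r}")
    if name == "dnn":
        layers = (
            {"kind": "flatten"},
            {"kind": "dense", "units": 256, "activation": "relu"},
            {"kind": "dropout", "rate": 0.5},
            {"kind": "dense", "units": 128, "activation": "relu"},
            {"kind": "dropout", "rate": 0.5},
            {"kind": "dense", "units": 64, "activation": "relu"},
            {"kind": "dense", "units": 1, "activation": "sigmoid"},
        )
        return ModelSpec(name, layers, input_shape)
    if t % 4 or m % 4:
        raise ValueError("CNN front end needs input dims divisible by 4")
    flat = (t // 4) * (m // 4) * 64
    if flat % t:
        raise ValueError("flattened CNN output does not reshape to "
                         f"{t} timesteps")
    kernels = {"bilstm": ((3, 3), (2, 3)),
               "cnn_lstm": ((3, 3), (3, 3)),
               "cnn_gru": ((2, 3), (3, 3))}[name]
    recurrent = {"bilstm": "bilstm", "cnn_lstm": "lstm",
                 "cnn_gru": "gru"}[name]
    layers = (
        {"kind": "conv2d", "filters": 32, "kernel": kernels[0],
         "activation": "relu", "padding": "same"},
        {"kind": "maxpool", "pool": (2, 2)},
        {"kind": "conv2d", "filters": 64, "kernel": kernels[1],
         "activation": "relu", "padding": "same"},
        {"kind": "maxpool", "pool": (2, 2)},
        {"kind": "flatten"},
        {"kind": "reshape", "timesteps": t, "features": flat // t},
        {"kind": recurrent, "units": 64, "return_sequences": True},
        {"kind": recurrent, "units": 32, "return_sequences": False},
        {"kind": "dense", "units": 64, "activation": "relu"},
        {"kind": "dropout", "rate": 0.5},
        {"kind": "dense", "units": 1, "activation": "sigmoid"},
    )
    return ModelSpec(name, layers, input_shape)


# ---------------------------------------------------------------------------
# concrete layers


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class _Dense:
    def __init__(self, rng, in_dim: int, units: int, activation: str):
        self.w = Tensor(_glorot(rng, in_dim, units, (in_dim, units)), True)
        self.b = Tensor(np.zeros(units), True)
        self.activation = activation

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor, rng, training) -> Tensor:
        out = x @ self.w + self.b
        if self.activation == "relu":
            return ag.relu(out)
        if self.activation == "sigmoid":
            return ag.sigmoid(out)
        return out


class _Conv:
    def __init__(self, rng, in_ch: int, desc: dict):
        kh, kw = desc["kernel"]
        filters = desc["filters"]
        fan_in = kh * kw * in_ch
        self.w = Tensor(_glorot(rng, fan_in, filters, (kh, kw, in_ch, filters)),
                        True)
        self.b = Tensor(np.zeros(filters), True)

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor, rng, training) -> Tensor:
        return ag.relu(ag.conv2d(x, self.w, self.b))


class _LSTMCell:
    def __init__(self, rng, in_dim: int, units: int):
        self.w = Tensor(_glorot(rng, in_dim + units, 4 * units,
                                (in_dim + units, 4 * units)), True)
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0  # forget-gate bias
        self.b = Tensor(b, True)
        self.units = units

    def params(self):
        return [self.w, self.b]

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        u = self.units
        z = ag.concat([x_t, h], axis=1) @ self.w + self.b
        i = ag.sigmoid(z[:, 0 * u:1 * u])
        f = ag.sigmoid(z[:, 1 * u:2 * u])
        g = ag.tanh(z[:, 2 * u:3 * u])
        o = ag.sigmoid(z[:, 3 * u:4 * u])
        c_new = f * c + i * g
        h_new = o * ag.tanh(c_new)
        return h_new, c_new


class _GRUCell:
    def __init__(self, rng, in_dim: int, units: int):
        self.w_zr = Tensor(_glorot(rng, in_dim + units, 2 * units,
                                   (in_dim + units, 2 * units)), True)
        self.b_zr = Tensor(np.zeros(2 * units), True)
        self.w_h = Tensor(_glorot(rng, in_dim + units, units,
                                  (in_dim + units, units)), True)
        self.b_h = Tensor(np.zeros(units), True)
        self.units = units

    def params(self):
        return [self.w_zr, self.b_zr, self.w_h, self.b_h]

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        u = self.units
        zr = ag.sigmoid(ag.concat([x_t, h], axis=1) @ self.w_zr + self.b_zr)
        z = zr[:, :u]
        r = zr[:, u:]
        h_tilde = ag.tanh(ag.concat([x_t, r * h], axis=1) @ self.w_h + self.b_h)
        one = Tensor(np.ones_like(z.data))
        return (one - z) * h + z * h_tilde  # update-gate blend


class _Recurrent:
    """LSTM / GRU layer, optionally bidirectional (concatenated states)."""

    def __init__(self, rng, in_dim: int, desc: dict):
        self.kind = desc["kind"]
        self.units = desc["units"]
        self.return_sequences = desc.get("return_sequences", False)
        make = _LSTMCell if self.kind in ("lstm", "bilstm") else _GRUCell
        self.fwd = make(rng, in_dim, self.units)
        self.bwd = make(rng, in_dim, self.units) if self.kind == "bilstm" else None

    def params(self):
        out = self.fwd.params()
        if self.bwd is not None:
            out = out + self.bwd.params()
        return out

    def _run(self, cell, xs: list[Tensor], n: int) -> list[Tensor]:
        h = Tensor(np.zeros((n, self.units)))
        outputs = []
        if isinstance(cell, _LSTMCell):
            c = Tensor(np.zeros((n, self.units)))
            for x_t in xs:
                h, c = cell.step(x_t, h, c)
                outputs.append(h)
        else:
            for x_t in xs:
                h = cell.step(x_t, h)
                outputs.append(h)
        return outputs

    def __call__(self, x: Tensor, rng, training) -> Tensor:
        n, T, _ = x.data.shape
        xs = [x[:, t, :] for t in range(T)]
        fwd_states = self._run(self.fwd, xs, n)
        if self.bwd is not None:
            bwd_states = self._run(self.bwd, xs[::-1], n)[::-1]
            states = [ag.concat([f, b], axis=1)
                      for f, b in zip(fwd_states, bwd_states)]
        else:
            states = fwd_states
        if self.return_sequences:
            width = states[0].data.shape[1]
            return ag.concat([s.reshape(n, 1, width) for s in states], axis=1)
        return states[-1]


class _Network:
    """Concrete layer stack instantiated from a ModelSpec."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers: list = []
        t, m = spec.input_shape
        shape: tuple = (t, m, 1)
        for desc in spec.layers:
            kind = desc["kind"]
            if kind == "conv2d":
                layer = _Conv(rng, shape[2], desc)
                shape = (shape[0], shape[1], desc["filters"])
            elif kind == "maxpool":
                layer = ("maxpool",)
                shape = (shape[0] // 2, shape[1] // 2, shape[2])
            elif kind == "flatten":
                layer = ("flatten",)
                shape = (int(np.prod(shape)),)
            elif kind == "reshape":
                layer = ("reshape", desc["timesteps"], desc["features"])
                shape = (desc["timesteps"], desc["features"])
            elif kind in ("lstm", "gru", "bilstm"):
                layer = _Recurrent(rng, shape[-1], desc)
                width = desc["units"] * (2 if kind == "bilstm" else 1)
                shape = (shape[0], width) if desc.get("return_sequences") \
                    else (width,)
            elif kind == "dense":
                layer = _Dense(rng, shape[-1], desc["units"], desc["activation"])
                shape = shape[:-1] + (desc["units"],)
            elif kind == "dropout":
                layer = ("dropout", desc["rate"])
            else:
                raise ValueError(f"unknown layer kind {kind!r}")
            self.layers.append(layer)

    def params(self) -> list[Tensor]:
        out = []
        for layer in self.layers:
            if hasattr(layer, "params"):
                out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def forward(self, x: np.ndarray, rng: np.random.Generator,
                training: bool) -> Tensor:
        has_conv = any(d["kind"] == "conv2d" for d in self.spec.layers)
        if has_conv:
            t = Tensor(x[..., None])  # (N, H, W, 1)
        else:
            t = Tensor(x)
        n = x.shape[0]
        for layer in self.layers:
            if isinstance(layer, tuple):
                if layer[0] == "maxpool":
                    t = ag.maxpool2x2(t)
                elif layer[0] == "flatten":
                    t = t.reshape(n, -1)
                elif layer[0] == "reshape":
                    t = t.reshape(n, layer[1], layer[2])
                elif layer[0] == "dropout":
                    t = ag.dropout(t, layer[1], rng, training)
            else:
                t = layer(t, rng, training)
        return t


class NeuralSequenceClassifier:
    """sklearn-style binary classifier over log-mel grids.

    Parameters
    ----------
    arch : str
        One of ``bilstm``, ``cnn_lstm``, ``cnn_gru``, ``dnn``.
    epochs : int or None
        Training epochs; ``None`` selects the architecture default
        (50 for cnn_lstm, 20 otherwise).
    learning_rate, batch_size, val_fraction :
        Adam learning rate, minibatch size, held-out validation share.
    random_state : int
        Seeds initialization, shuffling and dropout; identical seeds
        give bit-identical training runs.
    """

    def __init__(self, arch: str = "bilstm", epochs: int | None = None,
                 learning_rate: float = 0.001, batch_size: int = 16,
                 val_fraction: float = 0.2, random_state: int = 0,
                 input_shape: tuple[int, int] = (40, 128)):
        self.arch = arch
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.input_shape = input_shape

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("arch", "epochs", "learning_rate", "batch_size",
                 "val_fraction", "random_state", "input_shape")}

    def set_params(self, **params) -> "NeuralSequenceClassifier":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "NeuralSequenceClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int).ravel()
        if X.ndim == 2 and self.arch == "dnn":
            X = X.reshape(X.shape[0], *self.input_shape)
        if X.ndim != 3 or X.shape[1:] != tuple(self.input_shape):
            raise ValueError(f"expected input of shape (n, "
                             f"{self.input_shape[0]}, {self.input_shape[1]})")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = classes

        # standardize inputs (dB grids are far from unit scale)
        self.input_mean_ = float(X.mean())
        self.input_std_ = float(X.std()) or 1.0
        X = (X - self.input_mean_) / self.input_std_

        epochs = self.epochs or DEFAULT_EPOCHS[self.arch.lower()]
        rng = np.random.default_rng(self.random_state)
        self.spec_ = build_model(self.arch, self.input_shape)
        self._net = _Network(self.spec_, rng)
        self.n_parameters_ = self._net.n_parameters()
        optimizer = ag.Adam(self._net.params(), lr=self.learning_rate)

        # stratified train/validation split
        val_idx: list[int] = []
        for cls in classes:
            members = np.flatnonzero(y == cls)
            members = members[rng.permutation(members.size)]
            n_val = int(round(self.val_fraction * members.size))
            val_idx.extend(members[:n_val].tolist())
        val_mask = np.zeros(y.size, dtype=bool)
        val_mask[val_idx] = True
        if val_mask.all() or (~val_mask).sum() < 2:
            val_mask[:] = False
        train_idx = np.flatnonzero(~val_mask)
        X_tr, y_tr = X[train_idx], y[train_idx]

        self.history_ = {"loss": [], "accuracy": [],
                         "val_loss": [], "val_accuracy": []}
        for _ in range(epochs):
            order = rng.permutation(train_idx.size)
            epoch_loss, epoch_correct = 0.0, 0
            for start in range(0, order.size, self.batch_size):
                batch = order[start:start + self.batch_size]
                xb, yb = X_tr[batch], y_tr[batch]
                prob = self._net.forward(xb, rng, training=True)
                loss = ag.bce_loss(prob, yb.reshape(-1, 1))
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += float(loss.data) * batch.size
                epoch_correct += int(((prob.data.ravel() >= 0.5) == yb).sum())
            self.history_["loss"].append(epoch_loss / order.size)
            self.history_["accuracy"].append(epoch_correct / order.size)
            if val_mask.any():
                vp = self._net.forward(X[val_mask], rng, training=False)
                vl = ag.bce_loss(vp, y[val_mask].reshape(-1, 1))
                self.history_["val_loss"].append(float(vl.data))
                self.history_["val_accuracy"].append(
                    float(((vp.data.ravel() >= 0.5) == y[val_mask]).mean()))
        return self

    # -- inference ---------------------------------------------------------

    def _scores(self, X) -> np.ndarray:
        if not hasattr(self, "_net"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and self.arch == "dnn":
            X = X.reshape(X.shape[0], *self.input_shape)
        X = (X - self.input_mean_) / self.input_std_
        rng = np.random.default_rng(0)  # unused: dropout off at eval
        return self._net.forward(X, rng, training=False).data.ravel()

    def predict_proba(self, X) -> np.ndarray:
        p = self._scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self._scores(X) >= 0.5).astype(int)

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y).astype(int)).mean())


# ---------------------------------------------------------------------------
# classical baselines


DEFAULT_GRIDS = {
    "svm": {"clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale", 0.01]},
    "logreg": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "xgboost": {"clf__max_depth": [2, 3], "clf__n_estimators": [50, 100],
                "clf__learning_rate": [0.1, 0.3]},
}


def fit_classical(kind: str, X, y, hyper_grid: dict | None = None,
                  cv_folds: int = 3, seed: int = 0):
    """Fit one classical baseline with stratified grid-search CV.

    Returns the fitted :class:`sklearn.model_selection.GridSearchCV`
    (its ``best_estimator_`` is a scaler+classifier pipeline; XGBoost
    skips scaling, trees are scale-invariant).
    """
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    kind = kind.lower()
    if kind not in CLASSICAL_KINDS:
        raise ValueError(f"unknown classical model {kind!r}")
    if kind == "svm":
        from sklearn.svm import SVC
        steps = [("scale", StandardScaler()),
                 ("clf", SVC(kernel="rbf", probability=True,
                             random_state=seed))]
    elif kind == "logreg":
        from sklearn.linear_model import LogisticRegression
        steps = [("scale", StandardScaler()),
                 ("clf", LogisticRegression(max_iter=5000))]
    else:
        from xgboost import XGBClassifier
        steps = [("clf", XGBClassifier(eval_metric="logloss",
                                       random_state=seed))]
    grid = hyper_grid if hyper_grid is not None else DEFAULT_GRIDS[kind]
    if not grid:
        raise ValueError("hyper-parameter grid must be non-empty")
    search = GridSearchCV(
        Pipeline(steps), grid,
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        scoring="accuracy", n_jobs=1)
    search.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
    return search
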
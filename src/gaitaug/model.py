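"""A compact 4-block 2-D CNN classifier over spectrogram tensors.

Architecture: four blocks of [3x3 convolution -> batch normalization ->
ReLU -> 2x2 max-pooling], channel widths (16, 32, 64, 128), followed by
global average pooling and an affine map to two class logits with a
softmax. Pooling is clamped to size 1 along an axis whose feature map
is already a single cell. Training uses mini-batch Adam with L2 weight
decay on a cross-entropy loss.

The network is implemented directly on numpy (im2col convolutions,
hand-written backward passes), which keeps the whole pipeline
dependency-light and bit-deterministic under a fixed seed. Class index
0 is PD (the positive class), index 1 is HP; argmax tie-breaks to PD.

The default training hyperparameters are the study settings (300
epochs, batch 64, Adam, learning rate 1e-4, weight decay 1e-6); the
desk-scale experiment presets in :mod:`gaitaug.evaluate` override
epochs and learning rate for short runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import LABELS

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "CnnClassifier",
    "build_model",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.channels) < 1 or any(c < 1 for c in self.channels):
            raise ValueError("channels must be positive")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd (same-padding convolutions)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("learning_rate and weight_decay must be >= 0")


# ---------------------------------------------------------------------------
# im2col helpers (stride-1, same-padded square kernels).

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    B, C, H, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((B, C, k, k, H, W), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + H, j : j + W]
    return cols.reshape(B, C * k * k, H * W)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    B, C, H, W = x_shape
    p = k // 2
    dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dcols.dtype)
    d6 = dcols.reshape(B, C, k, k, H, W)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + H, j : j + W] += d6[:, :, i, j]
    return dxp[:, :, p : p + H, p : p + W]


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)
        B, _, H, W = x.shape
        W2 = self.W.reshape(self.W.shape[0], -1)
        out = np.matmul(W2, self._cols) + self.b[None, :, None]
        return out.reshape(B, self.W.shape[0], H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, Co, H, W = dout.shape
        d2 = dout.reshape(B, Co, H * W)
        self.dW = np.einsum("bol,bkl->ok", d2, self._cols).reshape(self.W.shape)
        self.db = d2.sum(axis=(0, 2))
        W2 = self.W.reshape(Co, -1)
        dcols = np.matmul(W2.T, d2)
        return _col2im(dcols, self._x_shape, self.k)

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm:
    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = 0.1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + _EPS).astype(np.float32)
        self._xhat = (x - mu[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = (self.gamma / self._std)[None, :, None, None]
        s1 = self.dbeta[None, :, None, None]
        s2 = self.dgamma[None, :, None, None]
        return g * (dout - (s1 + self._xhat * s2) / N)


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool:
    """2x2 max pooling; an axis already of size 1 is left unpooled, and
    a trailing odd row/column is dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        ph = 2 if H >= 2 else 1
        pw = 2 if W >= 2 else 1
        Hc, Wc = (H // ph) * ph, (W // pw) * pw
        self._x_shape, self._ph, self._pw = x.shape, ph, pw
        xv = x[:, :, :Hc, :Wc].reshape(B, C, Hc // ph, ph, Wc // pw, pw)
        xf = xv.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Hc // ph, Wc // pw, ph * pw)
        self._arg = xf.argmax(axis=-1)
        return np.take_along_axis(xf, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._x_shape
        ph, pw = self._ph, self._pw
        Hc, Wc = (H // ph) * ph, (W // pw) * pw
        Ho, Wo = Hc // ph, Wc // pw
        dxf = np.zeros((B, C, Ho, Wo, ph * pw), dtype=dout.dtype)
        np.put_along_axis(dxf, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dx[:, :, :Hc, :Wc] = (
            dxf.reshape(B, C, Ho, Wo, ph, pw).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Hc, Wc)
        )
        return dx


class _GlobalAvgPool:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._x_shape
        return np.broadcast_to(dout[:, :, None, None] / (H * W), self._x_shape).astype(dout.dtype)


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CnnClassifier:
    """The 4-block CNN; holds layers, forward/backward and parameters."""

    def __init__(self, cfg: ModelConfig, input_shape: tuple[int, int, int], seed: int = 0):
        c, h, w = input_shape
        if h < 1 or w < 1 or c < 1:
            raise ValueError(f"invalid input shape {input_shape}")
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_in = c
        for c_out in cfg.channels:
            self.layers += [_Conv(c_in, c_out, cfg.kernel, rng), _BatchNorm(c_out),
                            _ReLU(), _MaxPool()]
            c_in = c_out
        self.layers.append(_GlobalAvgPool())
        self.head = _Linear(c_in, cfg.n_classes, rng)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x, train=False))

    # -- parameter access ---------------------------------------------------
    def _param_grads(self):
        for layer in self.layers:
            if isinstance(layer, _Conv):
                yield layer, "W", "dW"
                yield layer, "b", "db"
            elif isinstance(layer, _BatchNorm):
                yield layer, "gamma", "dgamma"
                yield layer, "beta", "dbeta"
        yield self.head, "W", "dW"
        yield self.head, "b", "db"

    def parameters(self) -> list[np.ndarray]:
        return [getattr(obj, name) for obj, name, _ in self._param_grads()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for idx, (obj, name, _) in enumerate(self._param_grads()):
            out[f"p{idx}_{name}"] = getattr(obj, name)
        for idx, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm):
                out[f"bn{idx}_mean"] = layer.run_mean
                out[f"bn{idx}_var"] = layer.run_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for idx, (obj, name, _) in enumerate(self._param_grads()):
            setattr(obj, name, state[f"p{idx}_{name}"].copy())
        for idx, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm):
                layer.run_mean = state[f"bn{idx}_mean"].copy()
                layer.run_var = state[f"bn{idx}_var"].copy()


def build_model(cfg: ModelConfig, input_shape: tuple[int, int, int], seed: int = 0) -> CnnClassifier:
    """Initialise a seeded classifier for (channels, F, M) inputs."""
    return CnnClassifier(cfg, input_shape, seed)


class _Adam:
    def __init__(self, lr: float, wd: float):
        self.lr, self.wd = lr, wd
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, model: CnnClassifier) -> None:
        self.t += 1
        for i, (obj, name, gname) in enumerate(model._param_grads()):
            p = getattr(obj, name)
            g = getattr(obj, gname).astype(np.float32) + self.wd * p
            m = self.m.setdefault(i, np.zeros_like(p))
            v = self.v.setdefault(i, np.zeros_like(p))
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            setattr(obj, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def train(
    model: CnnClassifier,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> dict:
    """Mini-batch Adam training on cross-entropy.

    X: (N, C, F, M) spectrogram tensors; y: integer class indices
    (0 = PD, 1 = HP). The sample order is shuffled once from cfg.seed
    and reused every epoch, so a zero learning rate yields an exactly
    constant loss history. Returns {"loss": [...], "accuracy": [...]}
    per epoch.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class; need both PD and HP")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(X.shape[0])
    opt = _Adam(cfg.learning_rate, cfg.weight_decay)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    for _ in range(cfg.epochs):
        losses, correct = [], 0
        for start in range(0, X.shape[0], cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb, train=True)
            z = logits - logits.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            loss = -logp[np.arange(len(yb)), yb].mean()
            losses.append(float(loss) * len(yb))
            correct += int((logits.argmax(axis=1) == yb).sum())

            probs = np.exp(logp)
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model.backward(dlogits.astype(np.float32))
            opt.step(model)
        history["loss"].append(sum(losses) / X.shape[0])
        history["accuracy"].append(correct / X.shape[0])
    return history


def predict(model: CnnClassifier, tensors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels for a batch of tensors.

    Returns (probs, labels): probs has shape (N, 2) ordered (PD, HP);
    labels is an array of "PD"/"HP" strings. An exact probability tie
    resolves to PD, the positive class.
    """
    tensors = np.asarray(tensors, dtype=np.float32)
    if tensors.ndim == 3:
        tensors = tensors[None]
    if tensors.shape[1:] != model.input_shape:
        raise ValueError(f"input shape {tensors.shape[1:]} != model input {model.input_shape}")
    probs = model.predict_proba(tensors)
    labels = np.array([LABELS[i] for i in probs.argmax(axis=1)])
    return probs, labels


def save_checkpoint(model: CnnClassifier, path: str | Path) -> None:
    """Serialize parameters + config + seed to an .npz container."""
    meta = json.dumps(
        {"channels": list(model.cfg.channels), "kernel": model.cfg.kernel,
         "n_classes": model.cfg.n_classes, "input_shape": list(model.input_shape),
         "seed": model.seed}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_arrays())


def load_checkpoint(path: str | Path) -> CnnClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ModelConfig(channels=tuple(meta["channels"]), kernel=meta["kernel"],
                          n_classes=meta["n_classes"])
        model = CnnClassifier(cfg, tuple(meta["input_shape"]), seed=meta["seed"])
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model
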
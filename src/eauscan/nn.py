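"""Minimal CNN engine: layers, backprop and Adam, in pure numpy.

The classification network is small (a 3-filter grayscale adapter, a few
convolution blocks, global average pooling, dropout and a single sigmoid
unit), so an explicit im2col implementation with hand-written gradients is
fast enough on one CPU core and keeps the package free of heavyweight
deep-learning dependencies. Layers follow the usual forward/backward
contract; parameters live in per-layer dicts so freezing, cloning and
restoring best-epoch weights are plain dictionary operations.

Tensor layout is (N, C, H, W) throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: stateless unless it declares params."""

    trainable: bool = True
    group: str = "backbone"  # adapter | backbone | head

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learned state (e.g. running statistics) included in snapshots."""
        return {}

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3-style convolution with 'same' zero padding, stride 1 (im2col)."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, ksize, ksize))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"Conv2D expected {self.in_ch} input channels, got {c}")
        p = self.ksize // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = sliding_window_view(xp, (self.ksize, self.ksize), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        wmat = self.W.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w) = self._cache
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.dW = (dflat.T @ cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.W.reshape(self.out_ch, -1)
        dcols = dcols.reshape(n, h, w, c, self.ksize, self.ksize)
        p = self.ksize // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.ksize):
            for j in range(self.ksize):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2D(Layer):
    """Per-channel batch normalization; running statistics at inference."""

    # momentum 0.7 keeps the running statistics close to the batch statistics
    # after a handful of steps, which matters when epochs are only ~10 batches
    def __init__(self, channels: int, momentum: float = 0.7, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train=False, rng=None):
        # frozen BN runs in inference mode even while training (transfer-learning
        # convention): batch statistics are neither used nor accumulated
        if train and self.trainable:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            train = False
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, std, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        if not train:
            return dxhat / std[None, :, None, None]
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return term / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = dout[:, :, :, None, :, None] * self._mask
        return d.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float = 0.5):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.ravel()
    y = y.ravel().astype(float)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.reshape(-1, 1)


class SequentialNet:
    """An ordered layer stack with group-aware freezing and weight snapshots."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    # -- parameter bookkeeping ------------------------------------------------
    def parameterized(self) -> list[tuple[int, Layer]]:
        return [(i, l) for i, l in enumerate(self.layers) if l.params()]

    def set_trainable(self, groups: set[str], last_k_backbone: int | None = None) -> None:
        """Mark layer groups trainable; optionally only the last k parameterized
        backbone layers (the partial-unfreeze fine-tuning regime)."""
        backbone_param_layers = [l for _, l in self.parameterized() if l.group == "backbone"]
        allowed_backbone = set(
            id(l) for l in (backbone_param_layers[-last_k_backbone:] if last_k_backbone else backbone_param_layers)
        )
        for layer in self.layers:
            if layer.group == "backbone":
                layer.trainable = "backbone" in groups and id(layer) in allowed_backbone
            else:
                layer.trainable = layer.group in groups

    def trainable_params(self) -> list[tuple[str, Layer, str, np.ndarray]]:
        out = []
        for i, layer in self.parameterized():
            if layer.trainable:
                for name, arr in layer.params().items():
                    out.append((f"{i}.{name}", layer, name, arr))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                state[f"{i}.{name}"] = arr.copy()
            for name, arr in layer.buffers().items():
                state[f"{i}.buf.{name}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                arr[...] = state[f"{i}.{name}"]
            for name, arr in layer.buffers().items():
                arr[...] = state[f"{i}.buf.{name}"]

    def count_params(self, group: str | None = None, trainable_only: bool = False) -> int:
        total = 0
        for _, layer in self.parameterized():
            if group is not None and layer.group != group:
                continue
            if trainable_only and not layer.trainable:
                continue
            total += sum(a.size for a in layer.params().values())
        return total


class Adam:
    """Adam over a network's currently trainable parameters."""

    def __init__(self, net: SequentialNet, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for key, layer, name, arr in self.net.trainable_params():
            g = layer.grads()[name]
            if key not in self.m:
                self.m[key] = np.zeros_like(arr)
                self.v[key] = np.zeros_like(arr)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
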
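"""Efficient-channel-attention CNN for hybrid THz spectra, in pure NumPy.

Architecture: a 1-D convolution with 32 filters runs along the 240-point
frequency axis of the (alpha, n) input; its 32 filtered signals are stacked
into a single 240x32 two-dimensional feature map (the "input block").  Two
3x3 convolutions (32 channels each, batch norm, 2x2 max pooling), a 1x1
convolution to 64 channels, and the ECA module follow; ECA global-average
pools the channels, runs a k-tap 1-D convolution across neighboring
channels (k adapted to the channel count), applies a sigmoid, and rescales
each channel by its weight.  Dense layers 256 -> 128 -> n_classes with
softmax close the network.  Setting ``use_eca=False`` skips the attention
module, giving the plain-CNN ablation.

Training follows SGD with Nesterov momentum 0.9, initial learning rate
1e-3 with per-update decay lr_t = lr0/(1 + 1e-5 t), cross-entropy loss,
early stopping on validation loss, and a fine-tuning phase at 1e-4.

Everything — convolutions (im2col GEMM), batch norm, pooling, attention,
and their gradients — is implemented here in float32; no deep-learning
framework is used.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from thzamino import _kernels

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "AttentionState",
    "EcaNet",
    "adaptive_kernel_size",
    "eca_attention",
    "apply_attention",
    "build_network",
    "train",
    "predict",
    "input_block_feature_map",
]

_F32 = np.float32


def adaptive_kernel_size(C: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Cross-channel kernel size k = |log2(C)/gamma + b/gamma|_odd.

    Nearest odd integer, ties rounding up, floored at 1.  For the default
    (gamma=2, b=1) a 64-channel map gives k = 3.
    """
    if C < 1:
        raise ValueError("channel count must be >= 1")
    v = math.log2(C) / gamma + b / gamma
    k = 1 + 2 * math.floor((v - 1.0) / 2.0 + 0.5)
    return max(k, 1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class AttentionState:
    """Per-channel pooled averages and sigmoid attention weights."""

    pooled: np.ndarray
    weights: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")
        if np.any(self.weights <= 0) or np.any(self.weights >= 1):
            raise ValueError("attention weights must lie strictly in (0, 1)")


def _cross_channel_conv(y: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded k-tap convolution across the channel axis of y (B, C)."""
    k = kernel.size
    p = k // 2
    ypad = np.zeros((y.shape[0], y.shape[1] + 2 * p), dtype=y.dtype)
    ypad[:, p : p + y.shape[1]] = y
    s = np.zeros_like(y)
    for j in range(k):
        s += kernel[j] * ypad[:, j : j + y.shape[1]]
    return s


def eca_attention(feature_map: np.ndarray, kernel: np.ndarray | None = None, k: int = 3) -> AttentionState:
    """ECA weights for a (C, H, W) or (B, C, H, W) feature map.

    ``kernel`` holds the k cross-channel taps; ``None`` uses the identity
    tap (center one, rest zero), i.e. w_i = sigmoid(y_i).
    """
    x = np.asarray(feature_map, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("feature map must be (C, H, W) or (B, C, H, W)")
    if kernel is None:
        kernel = np.zeros(k)
        kernel[k // 2] = 1.0
    kernel = np.asarray(kernel, dtype=float).ravel()
    k = kernel.size
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    if k > x.shape[1]:
        raise ValueError("kernel size exceeds channel count")
    y = x.mean(axis=(2, 3))
    w = _sigmoid(_cross_channel_conv(y, kernel))
    if squeeze:
        y, w = y[0], w[0]
    return AttentionState(pooled=y, weights=w, k=k)


def apply_attention(feature_map: np.ndarray, att: AttentionState) -> np.ndarray:
    """Scale each channel of the map by its attention weight."""
    x = np.asarray(feature_map, dtype=float)
    w = np.asarray(att.weights, dtype=float)
    if x.ndim == 3:
        if w.shape != (x.shape[0],):
            raise ValueError("channel counts of map and attention differ")
        return x * w[:, None, None]
    if x.ndim == 4:
        if w.shape != x.shape[:2]:
            raise ValueError("channel counts of map and attention differ")
        return x * w[:, :, None, None]
    raise ValueError("feature map must be 3-D or 4-D")


# ---------------------------------------------------------------------------
# layers


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(_Layer):
    """Same-padded 1-D convolution over channels-last (B, L, C) input."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        scale = math.sqrt(2.0 / (in_ch * k))
        self.W = Param(rng.normal(0.0, scale, (k * in_ch, out_ch)).astype(_F32))
        self.b = Param(np.zeros(out_ch, dtype=_F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        B, L, C = x.shape
        k, p = self.k, self.k // 2
        xp = np.zeros((B, L + 2 * p, C), dtype=_F32)
        xp[:, p : p + L] = x
        cols = np.empty((B, L, k * C), dtype=_F32)
        for j in range(k):
            cols[:, :, j * C : (j + 1) * C] = xp[:, j : j + L]
        self._cols = cols.reshape(B * L, k * C)
        self._shape = (B, L, C)
        out = self._cols @ self.W.value + self.b.value
        return out.reshape(B, L, self.out_ch)

    def backward(self, g):
        B, L, C = self._shape
        k, p = self.k, self.k // 2
        g2 = g.reshape(B * L, self.out_ch)
        self.b.grad = g2.sum(axis=0)
        self.W.grad = self._cols.T @ g2
        dcols = (g2 @ self.W.value.T).reshape(B, L, k * C)
        dxp = np.zeros((B, L + 2 * p, C), dtype=_F32)
        for j in range(k):
            dxp[:, j : j + L] += dcols[:, :, j * C : (j + 1) * C]
        return dxp[:, p : p + L]


class StackTo2D(_Layer):
    """Stack the filtered 1-D signals into one single-channel 2-D map:
    (B, L, F) -> (B, H=L, W=F, 1)."""

    def forward(self, x, training):
        return x[..., None]

    def backward(self, g):
        return g[..., 0]


class Conv2D(_Layer):
    """Same-padded kxk 2-D convolution over channels-last (B, H, W, C)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        scale = math.sqrt(2.0 / (in_ch * k * k))
        self.W = Param(
            rng.normal(0.0, scale, (k * k * in_ch, out_ch)).astype(_F32)
        )
        self.b = Param(np.zeros(out_ch, dtype=_F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        B, H, W, C = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            self._cols = x.reshape(B * H * W, C)
        elif k == 3:
            xp = np.zeros((B, H + 2, W + 2, C), dtype=_F32)
            xp[:, 1 : 1 + H, 1 : 1 + W] = x
            cols = np.empty((B, H, W, 9 * C), dtype=_F32)
            _kernels.im2col3x3(xp, cols)
            self._cols = cols.reshape(B * H * W, 9 * C)
        else:
            xp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=_F32)
            xp[:, p : p + H, p : p + W] = x
            cols = np.empty((B, H, W, k * k * C), dtype=_F32)
            for i in range(k):
                for j in range(k):
                    s = (i * k + j) * C
                    cols[:, :, :, s : s + C] = xp[:, i : i + H, j : j + W]
            self._cols = cols.reshape(B * H * W, k * k * C)
        self._shape = (B, H, W, C)
        out = self._cols @ self.W.value + self.b.value
        return out.reshape(B, H, W, self.out_ch)

    def backward(self, g):
        B, H, W, C = self._shape
        k, p = self.k, self.k // 2
        g2 = g.reshape(B * H * W, self.out_ch)
        self.b.grad = g2.sum(axis=0)
        self.W.grad = self._cols.T @ g2
        dcols = g2 @ self.W.value.T
        if k == 1:
            return dcols.reshape(B, H, W, C)
        dcols = dcols.reshape(B, H, W, k * k * C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=dcols.dtype)
        if k == 3:
            _kernels.col2im3x3(dcols, dxp)
        else:
            for i in range(k):
                for j in range(k):
                    s = (i * k + j) * C
                    dxp[:, i : i + H, j : j + W] += dcols[:, :, :, s : s + C]
        return dxp[:, p : p + H, p : p + W]


class BatchNorm(_Layer):
    """Per-channel batch normalization for channels-last (B, H, W, C) maps."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=_F32))
        self.beta = Param(np.zeros(channels, dtype=_F32))
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(_F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        self._x, self._mean, self._inv = x, mean.astype(_F32), inv
        self._m = int(np.prod([x.shape[i] for i in axes]))
        self._training = training
        # fused scale-shift: out = a*x + c with per-channel a, c
        a = self.gamma.value * inv
        return a * x + (self.beta.value - self._mean * a)

    def backward(self, g):
        c = g.shape[-1]
        if self._training:
            g2 = np.ascontiguousarray(g).reshape(-1, c)
            x2 = np.ascontiguousarray(self._x).reshape(-1, c)
            dx, dgamma, dbeta = _kernels.bn_backward(
                x2, g2, self._mean, self._inv, self.gamma.value
            )
            self.gamma.grad = dgamma
            self.beta.grad = dbeta
            return dx.reshape(g.shape)
        axes = tuple(range(g.ndim - 1))
        xhat = (self._x - self._mean) * self._inv
        self.gamma.grad = (g * xhat).sum(axis=axes)
        self.beta.grad = g.sum(axis=axes)
        return g * self.gamma.value * self._inv


class ReLU(_Layer):
    def forward(self, x, training):
        self._out = np.maximum(x, 0.0)
        return self._out

    def backward(self, g):
        return g * (self._out > 0)


class MaxPool2x2(_Layer):
    """2x2 max pooling on channels-last maps, ties to the first element."""

    def forward(self, x, training):
        self._shape = x.shape
        out, self._idx = _kernels.maxpool2x2_forward(np.ascontiguousarray(x))
        return out

    def backward(self, g):
        _, H, W, _ = self._shape
        return _kernels.maxpool2x2_backward(np.ascontiguousarray(g), self._idx, H, W)


class ECALayer(_Layer):
    """Learned efficient channel attention on channels-last (B, H, W, C)."""

    def __init__(self, channels: int, gamma: float, b: float, rng: np.random.Generator):
        self.k = adaptive_kernel_size(channels, gamma, b)
        self.w = Param(rng.normal(0.0, 0.1, self.k).astype(_F32))

    def params(self):
        return [self.w]

    def forward(self, x, training):
        self._x = x
        self._hw = x.shape[1] * x.shape[2]
        y = x.mean(axis=(1, 2))
        k, p = self.k, self.k // 2
        ypad = np.zeros((y.shape[0], y.shape[1] + 2 * p), dtype=_F32)
        ypad[:, p : p + y.shape[1]] = y
        s = np.zeros_like(y)
        for j in range(k):
            s += self.w.value[j] * ypad[:, j : j + y.shape[1]]
        self._ypad = ypad
        self._a = _sigmoid(s)
        return x * self._a[:, None, None, :]

    def backward(self, g):
        a = self._a
        C = a.shape[1]
        k, p = self.k, self.k // 2
        da = (g * self._x).sum(axis=(1, 2))
        ds = (da * a * (1.0 - a)).astype(_F32)
        wg = np.empty(k, dtype=_F32)
        for j in range(k):
            wg[j] = (ds * self._ypad[:, j : j + C]).sum()
        self.w.grad = wg
        dypad = np.zeros_like(self._ypad)
        for j in range(k):
            dypad[:, j : j + C] += self.w.value[j] * ds
        dy = dypad[:, p : p + C]
        return g * a[:, None, None, :] + dy[:, None, None, :] / self._hw

    def attention_state(self, feature_map: np.ndarray) -> AttentionState:
        return eca_attention(feature_map, kernel=self.w.value.astype(float))


class Flatten(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, (n_in, n_out)).astype(_F32))
        self.b = Param(np.zeros(n_out, dtype=_F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        self.W.grad = self._x.T @ g
        self.b.grad = g.sum(axis=0)
        return g @ self.W.value.T


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class NetworkConfig:
    n_classes: int = 20
    input_length: int = 240
    input_channels: int = 2
    conv1_filters: int = 32
    conv1_kernel: int = 7
    conv23_channels: int = 32
    conv23_kernel: int = 3
    pool_size: int = 2
    conv4_channels: int = 64
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    fc_sizes: tuple[int, int] = (256, 128)
    use_eca: bool = True

    def __post_init__(self) -> None:
        if self.conv4_channels < 2:
            raise ValueError("conv4_channels must be >= 2")
        if any(s <= 0 for s in self.fc_sizes):
            raise ValueError("fc sizes must be positive")
        if self.eca_gamma <= 0:
            raise ValueError("eca_gamma must be > 0")
        if self.input_channels not in (1, 2):
            raise ValueError("input_channels must be 1 or 2")
        if self.input_length % 4 or self.conv1_filters % 4:
            raise ValueError(
                "input_length and conv1_filters must be divisible by 4 "
                "(two 2x2 pooling stages)"
            )


class EcaNet:
    """The assembled classifier; ``forward`` returns softmax probabilities."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.conv1 = Conv1D(c.input_channels, c.conv1_filters, c.conv1_kernel, rng)
        self.relu1 = ReLU()
        self.stack = StackTo2D()
        layers: list[_Layer] = [
            Conv2D(1, c.conv23_channels, c.conv23_kernel, rng),
            BatchNorm(c.conv23_channels),
            ReLU(),
            MaxPool2x2(),
            Conv2D(c.conv23_channels, c.conv23_channels, c.conv23_kernel, rng),
            BatchNorm(c.conv23_channels),
            ReLU(),
            MaxPool2x2(),
            Conv2D(c.conv23_channels, c.conv4_channels, 1, rng),
            BatchNorm(c.conv4_channels),
            ReLU(),
        ]
        self.eca: ECALayer | None = None
        if c.use_eca:
            self.eca = ECALayer(c.conv4_channels, c.eca_gamma, c.eca_b, rng)
            layers.append(self.eca)
        n_flat = (
            c.conv4_channels * (c.input_length // 4) * (c.conv1_filters // 4)
        )
        layers += [
            Flatten(),
            Dense(n_flat, c.fc_sizes[0], rng),
            ReLU(),
            Dense(c.fc_sizes[0], c.fc_sizes[1], rng),
            ReLU(),
            Dense(c.fc_sizes[1], c.n_classes, rng),
        ]
        self.body = layers

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self) -> list[_Layer]:
        return [self.conv1, self.relu1, self.stack, *self.body]

    def parameters(self) -> list[Param]:
        return [p for layer in self._all_layers() for p in layer.params()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- forward / backward ------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=_F32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.config.input_length or X.shape[2] != self.config.input_channels:
            raise ValueError(
                f"expected input (batch, {self.config.input_length}, "
                f"{self.config.input_channels}), got {X.shape}"
            )
        return X

    def forward_logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_input(X)  # channels-last (B, L, ch)
        for layer in self._all_layers():
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits.astype(_F32)
        for layer in reversed(self._all_layers()):
            g = layer.backward(g)

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        logits = self.forward_logits(X, training)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray, batch_size: int = 256):
        """Class probabilities and argmax labels (ties break to lowest index)."""
        X = np.asarray(X, dtype=_F32)
        if X.ndim == 2:
            X = X[None]
        if X.shape[0] == 0:
            return (
                np.empty((0, self.config.n_classes)),
                np.empty(0, dtype=int),
            )
        probs = np.concatenate(
            [
                self.forward(X[i : i + batch_size], training=False)
                for i in range(0, X.shape[0], batch_size)
            ]
        )
        return probs, probs.argmax(axis=1)

    def input_block_feature_map(self, item: np.ndarray) -> np.ndarray:
        """The stacked Conv1 output (length x filters) for one input item."""
        x = self._check_input(item)
        x = self.relu1.forward(self.conv1.forward(x, False), False)
        return x[0]

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.parameters()]
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def save(self, path) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        cfg = dict(asdict(self.config))
        cfg["fc_sizes"] = list(cfg["fc_sizes"])
        np.savez(path, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "EcaNet":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
        model = cls(NetworkConfig(**cfg))
        targets = model.state_arrays()
        for i, target in enumerate(targets):
            target[...] = data[f"arr_{i}"]
        return model


def build_network(cfg: NetworkConfig, seed: int = 0) -> EcaNet:
    """Construct the network of the architecture above from its config."""
    return EcaNet(cfg, seed=seed)


def input_block_feature_map(model: EcaNet, item: np.ndarray) -> np.ndarray:
    return model.input_block_feature_map(item)


def predict(model: EcaNet, X: np.ndarray):
    return model.predict(X)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingConfig:
    epochs: int = 300
    fine_tune_epochs: int = 100
    learning_rate: float = 1e-3
    fine_tune_lr: float = 1e-4
    lr_decay: float = 1e-5
    momentum: float = 0.9
    nesterov: bool = True
    batch_size: int = 128
    patience: int = 30


def _softmax_ce(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = y.size
    loss = float(-np.log(np.maximum(probs[np.arange(n), y], 1e-12)).mean())
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n, probs


def _eval_split(model: EcaNet, X: np.ndarray, y: np.ndarray, batch: int = 256):
    losses, correct = [], 0
    for i in range(0, X.shape[0], batch):
        logits = model.forward_logits(X[i : i + batch], training=False)
        loss, _, probs = _softmax_ce(logits, y[i : i + batch])
        losses.append(loss * (min(i + batch, X.shape[0]) - i))
        correct += int((probs.argmax(axis=1) == y[i : i + batch]).sum())
    return float(np.sum(losses) / X.shape[0]), correct / X.shape[0]


class _SGD:
    def __init__(self, params: list[Param], tcfg: TrainingConfig):
        self.params = params
        self.v = [np.zeros_like(p.value) for p in params]
        self.cfg = tcfg
        self.iterations = 0

    def step(self, lr0: float) -> None:
        lr = lr0 / (1.0 + self.cfg.lr_decay * self.iterations)
        mu = self.cfg.momentum
        kernel = (
            _kernels.sgd_nesterov_step if self.cfg.nesterov else _kernels.sgd_momentum_step
        )
        for p, v in zip(self.params, self.v):
            kernel(p.value.ravel(), v.ravel(), np.ascontiguousarray(p.grad).ravel(), lr, mu)
        self.iterations += 1


def train(
    model: EcaNet,
    train_set,
    val_set,
    tcfg: TrainingConfig = TrainingConfig(),
    seed: int = 0,
) -> tuple[EcaNet, dict]:
    """SGD/Nesterov training with early stopping and a fine-tuning phase.

    Returns the model (best-validation weights restored before fine-tuning)
    and a history dict with per-epoch train/val loss and accuracy.
    """
    Xtr = np.asarray(train_set.X, dtype=_F32)
    ytr = np.asarray(train_set.y, dtype=int)
    Xval = np.asarray(val_set.X, dtype=_F32)
    yval = np.asarray(val_set.y, dtype=int)
    if Xtr.shape[0] == 0 or Xval.shape[0] == 0:
        raise ValueError("train and validation splits must be non-empty")
    batch = tcfg.batch_size
    if batch > Xtr.shape[0]:
        warnings.warn(
            f"batch size {batch} exceeds the {Xtr.shape[0]} training items; "
            f"reduced to {Xtr.shape[0]}",
            stacklevel=2,
        )
        batch = Xtr.shape[0]

    rng = np.random.default_rng(seed)
    opt = _SGD(model.parameters(), tcfg)
    history = {k: [] for k in ("epoch", "train_loss", "val_loss", "train_acc", "val_acc")}

    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    since_best = 0

    def run_epoch(lr: float) -> tuple[float, float]:
        order = rng.permutation(Xtr.shape[0])
        losses, correct = [], 0
        for i in range(0, order.size, batch):
            sel = order[i : i + batch]
            model.zero_grad()
            logits = model.forward_logits(Xtr[sel], training=True)
            loss, dlogits, probs = _softmax_ce(logits, ytr[sel])
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss * sel.size)
            correct += int((probs.argmax(axis=1) == ytr[sel]).sum())
        return float(np.sum(losses) / order.size), correct / order.size

    def record(epoch: int, tr_loss: float, tr_acc: float) -> tuple[float, float]:
        val_loss, val_acc = _eval_split(model, Xval, yval)
        history["epoch"].append(epoch)
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(val_loss)
        history["train_acc"].append(tr_acc)
        history["val_acc"].append(val_acc)
        return val_loss, val_acc

    epoch = 0
    for _ in range(tcfg.epochs):
        tr_loss, tr_acc = run_epoch(tcfg.learning_rate)
        val_loss, _ = record(epoch, tr_loss, tr_acc)
        epoch += 1
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = [p.value.copy() for p in model.parameters()]
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                break

    if best_state is not None:
        for p, state in zip(model.parameters(), best_state):
            p.value[...] = state

    for _ in range(tcfg.fine_tune_epochs):
        tr_loss, tr_acc = run_epoch(tcfg.fine_tune_lr)
        record(epoch, tr_loss, tr_acc)
        epoch += 1

    return model, history


def write_history(path, history: dict) -> None:
    """Delimited-text training history (epoch, losses, accuracies)."""
    cols = ("epoch", "train_loss", "val_loss", "train_acc", "val_acc")
    data = np.column_stack([history[c] for c in cols])
    np.savetxt(path, data, header="\t".join(cols), delimiter="\t")
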
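"""Minimal numpy neural-network stack with manual backpropagation.

Everything the fusion model needs is built here from primitives:
2-D convolution (valid and same padding), 2x2 pooling with a learnable
per-channel scale/bias (the downsampling step is an affine map of the
pooled values passed through an activation), batch normalization,
dense layers, dropout, an LSTM, a class-weighted softmax cross-entropy
loss, and the Adam optimizer. All layers implement ``forward`` /
``backward`` and their analytic gradients are validated against central
finite differences in the test suite.

The module also exposes the five-layer base CNN used for internet-usage
feature extraction (conv - pool - conv - pool - fully connected), both as
standalone functional operations (``conv_forward``, ``pool_forward``,
``cnn_embed``) and as parameter initializers / counters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(x):
    return np.maximum(x, 0.0)


def identity(x):
    return x


ACTIVATIONS = {"relu": relu, "identity": identity, "linear": identity}


class Param:
    """A tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def _fan_in_uniform(rng, shape, fan_in):
    bound = math.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


# ---------------------------------------------------------------------------
# convolution primitives


def _conv2d(x, w, b, padding):
    """x: (N, C, H, W); w: (O, C, kh, kw); returns (N, O, Ho, Wo)."""
    kh, kw = w.shape[2], w.shape[3]
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        x = np.pad(x, ((0, 0), (0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw)))
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    o = w.shape[0]
    patches = sliding_window_view(x, (kh, kw), axis=(2, 3))
    n, c, ho, wo = patches.shape[:4]
    cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    out = cols @ w.reshape(o, -1).T
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    return out + b[None, :, None, None], x  # padded input cached


def _conv2d_backward(dout, x_padded, w, padding, in_shape, need_dx=True):
    """Gradients of _conv2d. Returns (dx, dw, db); dx is None when skipped."""
    o, c, kh, kw = w.shape
    patches = sliding_window_view(x_padded, (kh, kw), axis=(2, 3))
    n, _, ho, wo = patches.shape[:4]
    cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    dout_r = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
    dw = (dout_r.T @ cols).reshape(o, c, kh, kw)
    db = dout.sum(axis=(0, 2, 3))
    if not need_dx:
        return None, dw, db
    # full correlation of dout with the 180-degree-rotated kernels
    dpad = np.pad(dout, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    wrot = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dwin = sliding_window_view(dpad, (kh, kw), axis=(2, 3))
    hp, wp = dwin.shape[2], dwin.shape[3]
    dcols = dwin.transpose(0, 2, 3, 1, 4, 5).reshape(n * hp * wp, o * kh * kw)
    dxp = (dcols @ wrot.reshape(c, -1).T).reshape(n, hp, wp, c).transpose(0, 3, 1, 2)
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        H, W = in_shape[2], in_shape[3]
        dxp = dxp[:, :, ph : ph + H, pw : pw + W]
    return dxp, dw, db


def _pool_blocks(x):
    """Split (N, C, H, W) into 2x2 blocks with right/bottom zero pad.

    Returns (blocks, counts, padded_shape): blocks (N, C, H2, W2, 2, 2)
    and counts of genuine (unpadded) cells per block.
    """
    n, c, h, w = x.shape
    h2, w2 = -(-h // 2), -(-w // 2)
    xp = np.zeros((n, c, h2 * 2, w2 * 2))
    xp[:, :, :h, :w] = x
    mask = np.zeros((h2 * 2, w2 * 2))
    mask[:h, :w] = 1.0
    blocks = xp.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    counts = mask.reshape(h2, 2, w2, 2).transpose(0, 2, 1, 3).sum(axis=(2, 3))
    return blocks, counts, (h2, w2)


def _mean_pool(x):
    blocks, counts, (h2, w2) = _pool_blocks(x)
    down = blocks.sum(axis=(4, 5)) / counts[None, None]
    return down, counts


def _mean_pool_backward(ddown, counts, in_shape):
    n, c, h, w = in_shape
    h2, w2 = ddown.shape[2], ddown.shape[3]
    per_cell = ddown / counts[None, None]
    dxp = np.repeat(np.repeat(per_cell, 2, axis=2), 2, axis=3)
    return dxp[:, :, :h, :w]


# ---------------------------------------------------------------------------
# layers


class Layer:
    params: list = []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(
        self, in_ch, out_ch, ksize=3, padding="valid", rng=None, input_layer=False
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * ksize * ksize
        self.w = Param(_fan_in_uniform(rng, (out_ch, in_ch, ksize, ksize), fan_in))
        self.b = Param(np.zeros(out_ch))
        self.padding = padding
        self.input_layer = input_layer  # skip dx: the input is raw data
        self.params = [self.w, self.b]

    def forward(self, x, train=False):
        self._in_shape = x.shape
        out, self._xp = _conv2d(x, self.w.value, self.b.value, self.padding)
        return out

    def backward(self, dout):
        dx, dw, db = _conv2d_backward(
            dout,
            self._xp,
            self.w.value,
            self.padding,
            self._in_shape,
            need_dx=not self.input_layer,
        )
        self.w.grad += dw
        self.b.grad += db
        return dx


class Pool2D(Layer):
    """2x2 pooling followed by a learnable per-channel affine map.

    ``mode="mean"`` (default) averages each block; ``mode="max"`` takes the
    maximum. Odd spatial dims are padded on the right/bottom; mean pooling
    averages only genuine cells.
    """

    def __init__(self, channels, mode="mean", learnable=True):
        self.mode = mode
        self.learnable = learnable
        self.w = Param(np.ones(channels))
        self.b = Param(np.zeros(channels))
        self.params = [self.w, self.b] if learnable else []

    def forward(self, x, train=False):
        self._in_shape = x.shape
        if self.mode == "mean":
            down, self._counts = _mean_pool(x)
        elif self.mode == "max":
            blocks, _, _ = _pool_blocks(
                np.where(np.isfinite(x), x, x)  # copy-safe
            )
            n, c, h2, w2 = blocks.shape[:4]
            flat = blocks.reshape(n, c, h2, w2, 4)
            # padded zeros can win ties only when all real cells <= 0;
            # acceptable for the optional max mode
            self._argmax = flat.argmax(axis=-1)
            down = flat.max(axis=-1)
        else:
            raise ValueError(f"unknown pooling mode {self.mode!r}")
        self._down = down
        return down * self.w.value[None, :, None, None] + self.b.value[
            None, :, None, None
        ]

    def backward(self, dout):
        if self.learnable:
            self.w.grad += (dout * self._down).sum(axis=(0, 2, 3))
            self.b.grad += dout.sum(axis=(0, 2, 3))
        ddown = dout * self.w.value[None, :, None, None]
        if self.mode == "mean":
            return _mean_pool_backward(ddown, self._counts, self._in_shape)
        n, c, h, w = self._in_shape
        h2, w2 = ddown.shape[2], ddown.shape[3]
        dxp = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dxp, self._argmax[..., None], ddown[..., None], axis=-1)
        dxp = dxp.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dxp = dxp.reshape(n, c, h2 * 2, w2 * 2)
        return dxp[:, :, :h, :w]


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.params = [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        return (
            self.gamma.value[None, :, None, None] * self._xhat
            + self.beta.value[None, :, None, None]
        )

    def backward(self, dout):
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not self._train:
            return dxhat / std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        sum_d = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (dxhat - sum_d / m - xhat * sum_dx / m) / std[None, :, None, None]


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_fan_in_uniform(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out))
        self.params = [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` is True."""

    def __init__(self, rate, rng=None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if train and self.rate > 0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        else:
            self._mask = 1.0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(Layer):
    """Single-layer LSTM; emits the final hidden state.

    Input (N, T, d_in) -> output (N, h). Forget-gate bias initialized
    to 1.
    """

    def __init__(self, d_in, hidden, rng=None):
        rng = rng or np.random.default_rng(0)
        self.d_in, self.hidden = d_in, hidden
        self.wx = Param(_fan_in_uniform(rng, (d_in, 4 * hidden), d_in))
        self.wh = Param(_fan_in_uniform(rng, (hidden, 4 * hidden), hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Param(b)
        self.params = [self.wx, self.wh, self.b]

    def forward(self, x, train=False):
        n, t, _ = x.shape
        h = self.hidden
        self._x = x
        self._cache = []
        ht = np.zeros((n, h))
        ct = np.zeros((n, h))
        for step in range(t):
            z = x[:, step] @ self.wx.value + ht @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev, h_prev = ct, ht
            ct = f * c_prev + i * g
            ht = o * np.tanh(ct)
            self._cache.append((i, f, g, o, c_prev, h_prev, ct))
        return ht

    def backward(self, dout):
        x = self._x
        n, t, _ = x.shape
        h = self.hidden
        dht = dout
        dct = np.zeros((n, h))
        dx = np.zeros_like(x)
        for step in reversed(range(t)):
            i, f, g, o, c_prev, h_prev, ct = self._cache[step]
            tanh_c = np.tanh(ct)
            do = dht * tanh_c
            dct = dct + dht * o * (1 - tanh_c**2)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.wx.grad += x[:, step].T @ dz
            self.wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.value.T
            dht = dz @ self.wh.value.T
            dct = dct * f
        return dx


class SoftmaxCrossEntropy:
    """Class-weighted softmax cross-entropy over integer labels."""

    def forward(self, logits, labels, class_weights=None):
        n, k = logits.shape
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        w = np.ones(n) if class_weights is None else class_weights[labels]
        nll = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None))
        loss = float((w * nll).sum() / w.sum())
        self._probs, self._labels, self._w = probs, labels, w
        return loss, probs

    def backward(self):
        n, k = self._probs.shape
        grad = self._probs.copy()
        grad[np.arange(n), self._labels] -= 1.0
        grad *= (self._w / self._w.sum())[:, None]
        return grad


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the five-layer base CNN (conv - pool - conv - pool - fully connected)


@dataclass(frozen=True)
class BaseCnnSpec:
    """Architecture of the base internet-usage CNN."""

    conv1_kernels: int = 4
    conv2_kernels: int = 32
    ksize: int = 3
    fc_out: int = 16
    activation: str = "relu"
    pooling: str = "mean"
    seed: int = 0


def conv_forward(x, kernels, biases, activation="identity", padding="valid"):
    """Convolution layer: feature map j = f(sum_i x_i * k_ij + b_j).

    ``x`` may be (H, W), (C, H, W) or (N, C, H, W); ``kernels`` is
    (O, C, kh, kw); returns the same leading layout with O channels.
    """
    x = np.asarray(x, dtype=float)
    squeeze = 0
    if x.ndim == 2:
        x, squeeze = x[None, None], 2
    elif x.ndim == 3:
        x, squeeze = x[None], 1
    kernels = np.asarray(kernels, dtype=float)
    if kernels.shape[1] != x.shape[1]:
        raise ValueError(
            f"kernel input channels {kernels.shape[1]} != input channels {x.shape[1]}"
        )
    if kernels.shape[2] > x.shape[2] or kernels.shape[3] > x.shape[3]:
        raise ValueError("kernel larger than input")
    out, _ = _conv2d(x, kernels, np.asarray(biases, float), padding)
    out = ACTIVATIONS[activation](out)
    if squeeze == 2:
        return out[0, 0] if out.shape[1] == 1 else out[0]
    if squeeze == 1:
        return out[0]
    return out


def pool_forward(x, w=1.0, b=0.0, activation="identity", mode="mean"):
    """Pooling layer: f(w * down(x) + b), down = 2x2 pooling.

    ``w`` and ``b`` broadcast per channel; halves each spatial dimension
    (odd dims padded on the right/bottom).
    """
    x = np.asarray(x, dtype=float)
    squeeze = 0
    if x.ndim == 2:
        x, squeeze = x[None, None], 2
    elif x.ndim == 3:
        x, squeeze = x[None], 1
    if x.size == 0:
        raise ValueError("empty feature map")
    if mode == "mean":
        down, _ = _mean_pool(x)
    elif mode == "max":
        blocks, _, _ = _pool_blocks(x)
        down = blocks.max(axis=(4, 5))
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    w = np.asarray(w, float).reshape(-1)
    b = np.asarray(b, float).reshape(-1)
    out = ACTIVATIONS[activation](
        down * w[None, :, None, None] + b[None, :, None, None]
    )
    if squeeze == 2:
        return out[0, 0]
    if squeeze == 1:
        return out[0]
    return out


def _after_pool(d):
    return -(-d // 2)


def base_cnn_shapes(spec: BaseCnnSpec, input_shape):
    """Spatial shapes layer by layer for a (H, W) input, valid padding."""
    h, w = input_shape
    k = spec.ksize
    h1, w1 = h - k + 1, w - k + 1  # conv1 valid
    h2, w2 = _after_pool(h1), _after_pool(w1)  # pool1
    h3, w3 = h2 - k + 1, w2 - k + 1  # conv2 valid
    h4, w4 = _after_pool(h3), _after_pool(w3)  # pool2
    return (h1, w1), (h2, w2), (h3, w3), (h4, w4)


def init_base_cnn(spec: BaseCnnSpec, input_shape):
    """Initialize the five-layer base CNN for a (H, W) activity grid."""
    rng = np.random.default_rng(spec.seed)
    k = spec.ksize
    (_, _), (_, _), (_, _), (h4, w4) = base_cnn_shapes(spec, input_shape)
    if h4 < 1 or w4 < 1:
        raise ValueError(f"input {input_shape} too small for the architecture")
    layers = {
        "conv1": Conv2D(1, spec.conv1_kernels, k, "valid", rng),
        "pool1": Pool2D(spec.conv1_kernels, spec.pooling),
        "conv2": Conv2D(spec.conv1_kernels, spec.conv2_kernels, k, "valid", rng),
        "pool2": Pool2D(spec.conv2_kernels, spec.pooling),
        "fc": Dense(spec.conv2_kernels * h4 * w4, spec.fc_out, rng),
    }
    return layers


def cnn_embed(grid, spec: BaseCnnSpec, layers) -> np.ndarray:
    """Embedding of a single activity grid through the five-layer CNN.

    Hidden activations use the spec activation; the final fully connected
    output is linear. Deterministic given the layer parameters.
    """
    f = ACTIVATIONS[spec.activation]
    x = np.asarray(grid, dtype=float)[None, None]
    expected = layers["fc"].w.value.shape
    x = f(layers["conv1"].forward(x))
    x = f(layers["pool1"].forward(x))
    x = f(layers["conv2"].forward(x))
    x = f(layers["pool2"].forward(x))
    flat = x.reshape(1, -1)
    if flat.shape[1] != expected[0]:
        raise ValueError(
            f"spec/params mismatch: flattened width {flat.shape[1]} != {expected[0]}"
        )
    return layers["fc"].forward(flat)[0]


def base_cnn_param_count(spec: BaseCnnSpec, input_shape) -> int:
    """Closed-form parameter count of the five-layer base CNN."""
    k = spec.ksize
    (_, _), (_, _), (_, _), (h4, w4) = base_cnn_shapes(spec, input_shape)
    n = spec.conv1_kernels * (k * k * 1) + spec.conv1_kernels  # conv1 + bias
    n += 2 * spec.conv1_kernels  # pool1 w, b
    n += spec.conv2_kernels * (k * k * spec.conv1_kernels) + spec.conv2_kernels
    n += 2 * spec.conv2_kernels  # pool2 w, b
    n += spec.conv2_kernels * h4 * w4 * spec.fc_out + spec.fc_out
    return n


def numeric_gradient(fn, x, eps=1e-5):
    """Central-difference gradient of scalar ``fn`` w.r.t. array ``x``."""
    x = np.asarray(x, dtype=float)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = fn(x)
        x[idx] = orig - eps
        fm = fn(x)
        x[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
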
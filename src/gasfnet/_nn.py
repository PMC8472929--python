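"""Self-contained numpy neural-network core.

Layers implement explicit ``forward``/``backward`` passes (im2col-based
convolution, batch normalization, ReLU/SELU, pooling, linear head) plus a
softmax cross-entropy loss and an Adam optimizer.  Everything is plain
numpy so training is deterministic for a fixed seed on a fixed machine.

This is intentionally minimal: no graph autodiff, no GPU, float32 by
default.  The residual wiring (trunk + bypass sums, auxiliary shortcut
branches) lives in :mod:`gasfnet.resnet`, which composes these layers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

DEFAULT_DTYPE = np.float32


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int, pad_value: float = 0.0):
    """Extract (N*OH*OW, C*k*k) patch matrix from NCHW input."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(
            x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
            constant_values=pad_value,
        )
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    win = as_strided(
        x,
        shape=(n, oh, ow, c, k, k),
        strides=(s0, s2 * stride, s3 * stride, s1, s2, s3),
    )
    cols = win.reshape(n * oh * ow, c * k * k)  # forces a copy
    return cols, oh, ow, (hp, wp)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, oh: int, ow: int):
    """Scatter-add patch gradients back to the (unpadded) input."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    dc = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dc[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: parameter dict, gradient dict, train/eval flag."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    """2-D convolution without bias (batch norm always follows it here)."""

    def __init__(self, in_ch, out_ch, k, stride=1, pad=0, *, rng, gain=np.sqrt(2.0), dtype=DEFAULT_DTYPE):
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        fan_in = in_ch * k * k
        w = rng.normal(0.0, gain / np.sqrt(fan_in), size=(out_ch, in_ch, k, k))
        self.params["w"] = w.astype(dtype)
        self._cache = None

    def forward(self, x):
        cols, oh, ow, _ = _im2col(x, self.k, self.stride, self.pad)
        wm = self.params["w"].reshape(self.out_ch, -1)
        y = cols @ wm.T
        self._cache = (cols, x.shape, oh, ow)
        return y.reshape(x.shape[0], oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape, oh, ow = self._cache
        n = x_shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        wm = self.params["w"].reshape(self.out_ch, -1)
        self.grads["w"] = (dmat.T @ cols).reshape(self.params["w"].shape)
        dcols = dmat @ wm
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)


class BatchNorm2d(Layer):
    def __init__(self, ch, *, momentum=0.1, eps=1e-5, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.params["gamma"] = np.ones(ch, dtype=dtype)
        self.params["beta"] = np.zeros(ch, dtype=dtype)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self._cache = None

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * ivar[:, None, None]
        self._cache = (xhat, ivar.astype(x.dtype), self.training)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dout):
        xhat, ivar, was_training = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][:, None, None]
        dxhat = dout * g
        if not was_training:
            return dxhat * ivar[:, None, None]
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (ivar[:, None, None] / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


#: SELU constants of the self-normalizing fixed point.
SELU_ALPHA = 1.6733
SELU_LAMBDA = 1.0507


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class SELU(Layer):
    """Scaled exponential linear unit: lam*x (x>=0), lam*alpha*(e^x - 1) (x<0)."""

    def __init__(self, alpha=SELU_ALPHA, lam=SELU_LAMBDA):
        super().__init__()
        self.alpha, self.lam = alpha, lam

    def forward(self, x):
        pos = x >= 0
        neg_exp = np.exp(np.where(pos, 0.0, x))
        y = np.where(pos, self.lam * x, self.lam * self.alpha * (neg_exp - 1.0))
        self._cache = (pos, neg_exp)
        return y

    def backward(self, dout):
        pos, neg_exp = self._cache
        return dout * np.where(pos, self.lam, self.lam * self.alpha * neg_exp)


class MaxPool2d(Layer):
    def __init__(self, k=3, stride=2, pad=1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        cols, oh, ow, _ = _im2col(x, self.k, self.stride, self.pad, pad_value=-np.inf)
        n, c = x.shape[0], x.shape[1]
        patches = cols.reshape(n * oh * ow, c, self.k * self.k)
        idx = patches.argmax(axis=2)
        y = np.take_along_axis(patches, idx[:, :, None], axis=2)[:, :, 0]
        self._cache = (idx, x.shape, oh, ow)
        return y.reshape(n, oh, ow, c).transpose(0, 3, 1, 2)

    def backward(self, dout):
        idx, x_shape, oh, ow = self._cache
        n, c = x_shape[0], x_shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, c)
        dpatch = np.zeros((n * oh * ow, c, self.k * self.k), dtype=dout.dtype)
        np.put_along_axis(dpatch, idx[:, :, None], dmat[:, :, None], axis=2)
        dcols = dpatch.reshape(n * oh * ow, c * self.k * self.k)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)


class AvgPool2x2(Layer):
    """2x2 average pooling with stride 2 (even spatial sides only)."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"AvgPool2x2 needs even spatial sides, got {h}x{w}")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_f, out_f, *, rng, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.params["w"] = rng.normal(0.0, 1.0 / np.sqrt(in_f), size=(out_f, in_f)).astype(dtype)
        self.params["b"] = np.zeros(out_f, dtype=dtype)

    def forward(self, x):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def iter_layers(obj):
    """Depth-first iteration over all Layer instances reachable from obj."""
    if isinstance(obj, Layer):
        yield obj
        if isinstance(obj, Sequential):
            for sub in obj.layers:
                yield from iter_layers(sub)
    elif isinstance(obj, (list, tuple)):
        for sub in obj:
            yield from iter_layers(sub)


def set_training(layers, flag: bool) -> None:
    for layer in layers:
        layer.training = flag


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(n), targets], 1e-300)).mean())
    dlogits = p
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam with bias correction; operates on (layer, key) parameter slots."""

    def __init__(self, slots, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.slots = list(slots)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in self.slots]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in self.slots]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for i, (layer, key) in enumerate(self.slots):
            g = layer.grads.get(key)
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / c1
            vhat = self.v[i] / c2
            layer.params[key] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[key].dtype
            )


def param_slots(layers):
    """Stable (layer, key) list over all parameters, in construction order."""
    slots = []
    for layer in layers:
        for key in layer.params:
            slots.append((layer, key))
    return slots
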
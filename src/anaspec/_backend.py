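"""Minimal NumPy neural-network backend: NHWC conv/pool/dense layers with
explicit forward/backward passes, softmax cross-entropy, and SGD/Adam.

All tensors are float32; convolution is im2col + GEMM.  The backend is
deliberately small — just what the architecture registry needs — and fully
deterministic for a fixed RNG.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _pad_same(h: int, w: int, kh: int, kw: int, sh: int, sw: int):
    """Per-axis (before, after) zero padding for same-style output ceil(n/s)."""
    oh, ow = -(-h // sh), -(-w // sw)
    ph = max((oh - 1) * sh + kh - h, 0)
    pw = max((ow - 1) * sw + kw - w, 0)
    return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,H,W,C) -> (N,OH,OW, kh*kw*C) patch matrix."""
    view = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::sh, ::sw]
    # view: (N, OH, OW, C, kh, kw) -> (N, OH, OW, kh, kw, C)
    view = view.transpose(0, 1, 2, 4, 5, 3)
    n, oh, ow = view.shape[:3]
    return np.ascontiguousarray(view).reshape(n, oh, ow, kh * kw * x.shape[3])


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, sh: int, sw: int):
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, h, w, c = x_shape
    _, oh, ow, _ = dcols.shape
    dcols = dcols.reshape(n, oh, ow, kh, kw, c)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, i:i + sh * oh:sh, j:j + sw * ow:sw, :] += dcols[:, :, :, i, j, :]
    return dx


class Layer:
    """Base: parameter-free identity."""

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, in_channels, filters, kernel, stride, padding,
                 rng: np.random.Generator, activation="relu"):
        kh, kw = kernel
        fan_in = kh * kw * in_channels
        self.W = (rng.standard_normal((fan_in, filters))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        kh, kw = self.kernel
        sh, sw = self.stride
        self._unpadded = (x.shape[1], x.shape[2])
        if self.padding == "same":
            (pt, pb), (pl, pr) = _pad_same(x.shape[1], x.shape[2], kh, kw, sh, sw)
            x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(x, kh, kw, sh, sw)
        out = cols @ self.W + self.b
        if train:
            self._x_shape, self._cols = x.shape, cols
        if self.activation == "relu":
            out = np.maximum(out, 0.0)
            if train:
                self._mask = out > 0
        return out

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._mask
        kh, kw = self.kernel
        sh, sw = self.stride
        k = self._cols.shape[-1]
        f = self.W.shape[1]
        cols2d = self._cols.reshape(-1, k)
        dout2d = dout.reshape(-1, f)
        self.dW[...] = cols2d.T @ dout2d
        self.db[...] = dout2d.sum(axis=0)
        dcols = dout2d @ self.W.T
        dx = _col2im(dcols.reshape(dout.shape[:3] + (k,)),
                     self._x_shape, kh, kw, sh, sw)
        if self.padding == "same":
            # padding was applied inside forward; crop it back off
            ph = self._x_shape[1] - self._unpadded[0]
            pw = self._x_shape[2] - self._unpadded[1]
            pt, pl = ph // 2, pw // 2
            dx = dx[:, pt:pt + self._unpadded[0], pl:pl + self._unpadded[1], :]
        self._cols = None
        return dx


class MaxPool2D(Layer):
    def __init__(self, kernel, stride):
        self.kernel, self.stride = kernel, stride

    def forward(self, x, train=False):
        kh, kw = self.kernel
        sh, sw = self.stride
        view = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::sh, ::sw]
        flat = np.ascontiguousarray(view).reshape(view.shape[:4] + (kh * kw,))
        out = flat.max(axis=-1)
        if train:
            self._x_shape = x.shape
            self._arg = flat.argmax(axis=-1)
        return out

    def backward(self, dout):
        kh, kw = self.kernel
        sh, sw = self.stride
        n, oh, ow, c = dout.shape
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        for idx in range(kh * kw):
            i, j = divmod(idx, kw)
            mask = self._arg == idx
            contrib = np.where(mask, dout, 0.0)
            dx[:, i:i + sh * oh:sh, j:j + sw * ow:sw, :] += contrib
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, units, rng: np.random.Generator,
                 activation="relu"):
        self.W = (rng.standard_normal((in_features, units))
                  * np.sqrt(2.0 / in_features)).astype(np.float32)
        self.b = np.zeros(units, dtype=np.float32)
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        out = x @ self.W + self.b
        if train:
            self._x = x
        if self.activation == "relu":
            out = np.maximum(out, 0.0)
            if train:
                self._mask = out > 0
        return out  # softmax handled by the loss

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._mask
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout on dense activations (identity at inference)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def forward_shapes(self, x):
        """Actual activation shape after every layer (shape-audit hook)."""
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            shapes.append(x.shape[1:])
        return shapes

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr=1e-3, momentum=0.9):
        self.params, self.lr, self.momentum = params, lr, momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, g, v in zip(self.params, grads, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= corr * m / (np.sqrt(v) + self.eps)
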
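"""Minimal NumPy neural-network layers with exact backpropagation.

Implements exactly the layer set the segmentation network needs: stride-1
"same" convolutions (im2col + BLAS GEMM), 2x2/stride-2 max pooling,
non-overlapping transposed convolutions (kernel = stride), a full-image
"fully-connected-like" convolution, ReLU, and Adam.  Data layout is NHWC;
float32 by default (float64 for gradient checking).

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients in ``grads`` during ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "MaxPool2", "Deconv", "FullConv", "Adam"]


def _he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class _Layer:
    """Base: named parameter/gradient dictionaries."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self):
        for k in self.params:
            g = self.grads.get(k)
            if g is None or g.shape != self.params[k].shape:
                self.grads[k] = np.zeros_like(self.params[k])
            else:
                g.fill(0)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix under same zero-padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    v = sliding_window_view(xp, (k, k), axis=(1, 2))   # N,H,W,C,k,k
    v = v.transpose(0, 1, 2, 4, 5, 3)                  # N,H,W,k,k,C
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(v).reshape(n * h * w, k * k * x.shape[3])


class Conv2D(_Layer):
    """Stride-1 convolution with same zero-padding, optional fused ReLU."""

    def __init__(self, cin: int, cout: int, k: int,
                 rng: np.random.Generator, dtype=np.float32,
                 relu: bool = True, name: str = "",
                 weight_scale: float = 1.0, bias_init: float = 0.0):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("same-padding convolution needs an odd kernel")
        self.cin, self.cout, self.k = cin, cout, k
        self.relu = relu
        self.name = name
        self.params["W"] = weight_scale * _he_uniform(
            rng, (k, k, cin, cout), k * k * cin, dtype)
        self.params["b"] = np.full(cout, bias_init, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        if self.k == 1:
            col = x.reshape(-1, self.cin)
        else:
            col = _im2col(x, self.k)
        self._col = col
        self._in_shape = x.shape
        y = col @ self.params["W"].reshape(-1, self.cout) + self.params["b"]
        y = y.reshape(n, h, w, self.cout)
        if self.relu:
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        if self.relu:
            dy = dy * self._mask
        n, h, w, _ = dy.shape
        dyf = dy.reshape(-1, self.cout)
        self.grads["W"] += (self._col.T @ dyf).reshape(self.params["W"].shape)
        self.grads["b"] += dyf.sum(axis=0)
        if not need_dx:
            return None
        W = self.params["W"]
        if self.k == 1:
            dx = dyf @ W.reshape(self.cin, self.cout).T
            return dx.reshape(self._in_shape)
        # full correlation of dy with the spatially flipped kernel
        Wrot = W[::-1, ::-1].transpose(0, 1, 3, 2)     # k,k,cout,cin
        col = _im2col(dy, self.k)
        dx = col @ Wrot.reshape(-1, self.cin)
        return dx.reshape(self._in_shape)


class MaxPool2(_Layer):
    """2x2 max pooling with stride 2 (requires even H and W)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dimensions")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        windows = xr.transpose(0, 1, 3, 5, 2, 4).reshape(-1, 4)
        self._argmax = windows.argmax(axis=1)
        self._shape = x.shape
        return windows[np.arange(windows.shape[0]), self._argmax].reshape(
            n, h // 2, w // 2, c)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        n, h, w, c = self._shape
        flat = np.zeros((n * (h // 2) * (w // 2) * c, 4), dtype=dy.dtype)
        flat[np.arange(flat.shape[0]), self._argmax] = dy.ravel()
        dx = flat.reshape(n, h // 2, w // 2, c, 2, 2)
        dx = dx.transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        return dx


class Deconv(_Layer):
    """Transposed convolution with kernel = stride (non-overlapping tiles).

    Maps (N, h, w, cin) -> (N, h*r, w*r, cout); each input pixel paints an
    r x r output tile.  This covers both the 1x1 -> (S/16) reconstruction
    (r = S/16) and the resolution-doubling blocks (r = 2).
    """

    def __init__(self, cin: int, cout: int, r: int,
                 rng: np.random.Generator, dtype=np.float32, name: str = "",
                 weight_scale: float = 1.0):
        super().__init__()
        self.cin, self.cout, self.r = cin, cout, r
        self.name = name
        self.params["W"] = weight_scale * _he_uniform(
            rng, (r, r, cin, cout), cin, dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        r = self.r
        self._xf = x.reshape(-1, self.cin)
        W2 = self.params["W"].transpose(2, 0, 1, 3).reshape(self.cin, -1)
        y = self._xf @ W2 + np.tile(self.params["b"], r * r)
        y = y.reshape(n, h, w, r, r, self.cout)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, h * r, w * r, self.cout)
        self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        n, h, w, _ = self._in_shape
        r = self.r
        dy6 = dy.reshape(n, h, r, w, r, self.cout).transpose(0, 1, 3, 2, 4, 5)
        dyf = dy6.reshape(-1, r * r * self.cout)
        dW = (self._xf.T @ dyf).reshape(self.cin, r, r, self.cout)
        self.grads["W"] += dW.transpose(1, 2, 0, 3)
        self.grads["b"] += dyf.reshape(-1, r * r, self.cout).sum(axis=(0, 1))
        if not need_dx:
            return None
        W2 = self.params["W"].transpose(2, 0, 1, 3).reshape(self.cin, -1)
        dx = dyf @ W2.T
        return dx.reshape(self._in_shape)


class FullConv(_Layer):
    """Valid convolution whose kernel equals the full input map.

    Every output neuron sees every input neuron ("fully-connected-like");
    output is (N, 1, 1, cout).  Fused ReLU optional.
    """

    def __init__(self, h: int, w: int, cin: int, cout: int,
                 rng: np.random.Generator, dtype=np.float32,
                 relu: bool = True, name: str = ""):
        super().__init__()
        self.h, self.w, self.cin, self.cout = h, w, cin, cout
        self.relu = relu
        self.name = name
        fan_in = h * w * cin
        self.params["W"] = _he_uniform(rng, (fan_in, cout), fan_in, dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        if x.shape[1:] != (self.h, self.w, self.cin):
            raise ValueError(f"{self.name}: expected map "
                             f"{(self.h, self.w, self.cin)}, got {x.shape[1:]}")
        self._xf = x.reshape(n, -1)
        y = self._xf @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = y > 0
            y = y * self._mask
        return y.reshape(n, 1, 1, self.cout)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout)
        if self.relu:
            dyf = dyf * self._mask
        self.grads["W"] += self._xf.T @ dyf
        self.grads["b"] += dyf.sum(axis=0)
        if not need_dx:
            return None
        dx = dyf @ self.params["W"].T
        return dx.reshape(n, self.h, self.w, self.cin)


class Adam:
    """Adam optimiser over a list of (layer, param-name) handles."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.handles = [(layer, name) for layer in layers
                        for name in layer.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[n]) for l, n in self.handles]
        self.v = [np.zeros_like(l.params[n]) for l, n in self.handles]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[name] -= (self.lr * mhat
                                   / (np.sqrt(vhat) + self.eps)).astype(
                                       layer.params[name].dtype)

    def zero_grad(self):
        seen = set()
        for layer, _ in self.handles:
            if id(layer) not in seen:
                layer.zero_grad()
                seen.add(id(layer))

    def reset_layer(self, layer):
        """Clear first/second-moment state for one layer's parameters."""
        for i, (lay, _name) in enumerate(self.handles):
            if lay is layer:
                self.m[i] = np.zeros_like(self.m[i])
                self.v[i] = np.zeros_like(self.v[i])
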
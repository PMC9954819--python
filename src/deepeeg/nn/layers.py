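"""Feed-forward layers (NHWC layout) with analytic gradients."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Sequential",
    "Conv2D",
    "MaxPool2D",
    "Upsample2D",
    "CropOrPadToShape",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "Flatten",
    "ToSequence",
]


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @params.setter
    def params(self, value):  # base-class __init__ compatibility
        pass

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _uniform_init(rng, shape, fan_in, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def _mm_last(a, m):
    """``a @ m`` over the last axis, avoiding degenerate BLAS shapes.

    ``a`` is (..., k), ``m`` is (k, c).  An inner dimension of 1 is a pure
    broadcast and is dispatched as one, which is orders of magnitude faster
    than a batched rank-1 gemm.
    """
    if m.shape[0] == 1:
        return a * m[0]
    return a @ m


class Conv2D(Layer):
    """2-D convolution, stride 1, same zero padding, odd kernel.

    Computed as a sum of kernel-shift matmuls over the padded input, which
    keeps memory traffic proportional to the tensor size (an im2col
    materialization is kh*kw-fold larger).  ``skip_input_grad`` elides the
    input-gradient pass for a network's first layer.
    """

    def __init__(self, in_channels, out_channels, kernel=3, rng=None,
                 dtype=np.float32, skip_input_grad=False):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng()
        self.kh = self.kw = kernel
        self.skip_input_grad = skip_input_grad
        fan_in = kernel * kernel * in_channels
        self.W = _uniform_init(rng, (kernel, kernel, in_channels, out_channels),
                               fan_in, dtype)
        self.b = _uniform_init(rng, (out_channels,), fan_in, dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self._xp = None

    def forward(self, x, train=False):
        n, h, w, cin = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        self._xp = xp
        self._hw = (h, w)
        y = np.zeros((n, h, w, self.W.shape[3]), dtype=x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                y += _mm_last(xp[:, i : i + h, j : j + w], self.W[i, j])
        return y + self.b

    def backward(self, dy):
        xp = self._xp
        h, w = self._hw
        n = dy.shape[0]
        cin, cout = self.W.shape[2], self.W.shape[3]
        dyf = dy.reshape(-1, cout)
        self.db[...] = dyf.sum(axis=0)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = np.ascontiguousarray(
                    xp[:, i : i + h, j : j + w]
                ).reshape(-1, cin)
                self.dW[i, j] = xs.T @ dyf
        if self.skip_input_grad:
            return None
        dxp = np.zeros_like(xp)
        wt = self.W.transpose(0, 1, 3, 2)  # (kh, kw, cout, cin)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i : i + h, j : j + w] += _mm_last(
                    dy, np.ascontiguousarray(wt[i, j])
                )
        ph, pw = self.kh // 2, self.kw // 2
        return dxp[:, ph : ph + h, pw : pw + w]


class MaxPool2D(Layer):
    """Max pooling with independent per-axis factors; remainder is cropped."""

    def __init__(self, pool_h=2, pool_w=2):
        super().__init__()
        self.ph, self.pw = pool_h, pool_w

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        h2, w2 = h // ph, w // pw
        # window-last layout so argmax/scatter run on one contiguous axis
        xr = (
            x[:, : h2 * ph, : w2 * pw]
            .reshape(n, h2, ph, w2, pw, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h2, w2, c, ph * pw)
        )
        self._idx = xr.argmax(axis=4)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=4)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        ph, pw = self.ph, self.pw
        h2, w2 = h // ph, w // pw
        dxr = np.zeros((n, h2, w2, c, ph * pw), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=4)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : h2 * ph, : w2 * pw] = (
            dxr.reshape(n, h2, w2, c, ph, pw)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h2 * ph, w2 * pw, c)
        )
        return dx


class Upsample2D(Layer):
    """Nearest-neighbour upsampling by integer factors, then fitted to a
    target spatial shape (crop from, or edge-replicate at, the bottom/right
    to undo floor losses of the matching pooling stage)."""

    def __init__(self, factor_h=2, factor_w=2, target_hw=None):
        super().__init__()
        self.fh, self.fw = factor_h, factor_w
        self.target_hw = target_hw

    def forward(self, x, train=False):
        self._in_shape = x.shape
        y = x.repeat(self.fh, axis=1).repeat(self.fw, axis=2)
        self._up_shape = y.shape
        if self.target_hw is not None:
            th, tw = self.target_hw
            h, w = y.shape[1], y.shape[2]
            if th < h:
                y = y[:, :th]
            elif th > h:
                y = np.concatenate(
                    [y, np.repeat(y[:, -1:], th - h, axis=1)], axis=1
                )
            if tw < w:
                y = y[:, :, :tw]
            elif tw > w:
                y = np.concatenate(
                    [y, np.repeat(y[:, :, -1:], tw - w, axis=2)], axis=2
                )
        return y

    def backward(self, dy):
        n, hu, wu, c = self._up_shape
        if self.target_hw is not None:
            th, tw = dy.shape[1], dy.shape[2]
            if tw > wu:  # undo right edge-pad
                extra = dy[:, :, wu:].sum(axis=2)
                dy = dy[:, :, :wu].copy()
                dy[:, :, -1] += extra
            elif tw < wu:
                dy = np.concatenate(
                    [dy, np.zeros((dy.shape[0], th, wu - tw, c), dtype=dy.dtype)],
                    axis=2,
                )
            if th > hu:  # undo bottom edge-pad
                extra = dy[:, hu:].sum(axis=1)
                dy = dy[:, :hu].copy()
                dy[:, -1] += extra
            elif th < hu:
                dy = np.concatenate(
                    [dy, np.zeros((dy.shape[0], hu - th, wu, c), dtype=dy.dtype)],
                    axis=1,
                )
        n0, h0, w0, _ = self._in_shape
        return dy.reshape(n0, h0, self.fh, w0, self.fw, c).sum(axis=(2, 4))


class CropOrPadToShape(Layer):
    """Fit the spatial dims to a target by bottom/right crop or zero pad."""

    def __init__(self, target_hw):
        super().__init__()
        self.target_hw = target_hw

    def forward(self, x, train=False):
        self._in_shape = x.shape
        th, tw = self.target_hw
        n, h, w, c = x.shape
        if h > th:
            x = x[:, :th]
        elif h < th:
            x = np.pad(x, ((0, 0), (0, th - h), (0, 0), (0, 0)))
        if w > tw:
            x = x[:, :, :tw]
        elif w < tw:
            x = np.pad(x, ((0, 0), (0, 0), (0, tw - w), (0, 0)))
        return x

    def backward(self, dy):
        n, h, w, c = self._in_shape
        th, tw = self.target_hw
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : min(h, th), : min(w, tw)] = dy[:, : min(h, th), : min(w, tw)]
        return dx


class Dense(Layer):
    """Affine map on the last axis (works for 2-D and 3-D inputs)."""

    def __init__(self, in_features, out_features, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.W = _uniform_init(rng, (in_features, out_features), in_features, dtype)
        self.b = _uniform_init(rng, (out_features,), in_features, dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x2 = self._x.reshape(-1, self.W.shape[0])
        dy2 = dy.reshape(-1, self.W.shape[1])
        self.dW[...] = x2.T @ dy2
        self.db[...] = dy2.sum(axis=0)
        return (dy2 @ self.W.T).reshape(self._x.shape)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; ``rate`` is the probability of dropping a unit."""

    def __init__(self, rate, rng=None):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (
            self.rng.random(x.shape) < keep
        ).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ToSequence(Layer):
    """(N, H, W, C) -> (N, W, H*C): the reduced time axis becomes the
    sequence dimension, electrode-by-feature maps the per-step features."""

    def forward(self, x, train=False):
        self._shape = x.shape
        n, h, w, c = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, w, h * c)

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.ascontiguousarray(
            dy.reshape(n, w, h, c).transpose(0, 2, 1, 3)
        )
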
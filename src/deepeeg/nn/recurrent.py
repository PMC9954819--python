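"""Recurrent layers: LSTM, bidirectional wrapper, temporal pooling.

Inputs are batch-first sequences (N, T, F).  The LSTM uses the standard
gate parameterization (input, forget, cell, output) with a +1 forget-gate
bias at initialization; gradients are computed by full backpropagation
through time.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, _uniform_init

__all__ = ["LSTM", "Bidirectional", "TemporalMeanPool"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Unidirectional LSTM returning the full output sequence (N, T, H)."""

    def __init__(self, input_size, hidden_size, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.input_size = input_size
        self.hidden = hidden_size
        h = hidden_size
        self.Wx = _uniform_init(rng, (input_size, 4 * h), input_size, dtype)
        self.Wh = _uniform_init(rng, (h, 4 * h), h, dtype)
        self.b = np.zeros(4 * h, dtype=dtype)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [self.dWx, self.dWh, self.db]

    def forward(self, x, train=False):
        n, t, f = x.shape
        h = self.hidden
        self._x = x
        xa = x.reshape(n * t, f) @ self.Wx
        xa = xa.reshape(n, t, 4 * h)
        hs = np.zeros((n, t, h), dtype=x.dtype)
        self._cache = []
        h_prev = np.zeros((n, h), dtype=x.dtype)
        c_prev = np.zeros((n, h), dtype=x.dtype)
        for step in range(t):
            a = xa[:, step] + h_prev @ self.Wh + self.b
            i = _sigmoid(a[:, :h])
            f_ = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c = f_ * c_prev + i * g
            tc = np.tanh(c)
            hs[:, step] = o * tc
            self._cache.append((i, f_, g, o, c_prev, tc, h_prev))
            h_prev = hs[:, step]
            c_prev = c
        return hs

    def backward(self, dy):
        x = self._x
        n, t, f = x.shape
        h = self.hidden
        self.dWx[...] = 0
        self.dWh[...] = 0
        self.db[...] = 0
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h), dtype=x.dtype)
        dc_next = np.zeros((n, h), dtype=x.dtype)
        da_all = np.zeros((n, t, 4 * h), dtype=x.dtype)
        for step in reversed(range(t)):
            i, f_, g, o, c_prev, tc, h_prev = self._cache[step]
            dh = dy[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f_
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f_ * (1.0 - f_),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            da_all[:, step] = da
            self.dWh += h_prev.T @ da
            dh_next = da @ self.Wh.T
        da2 = da_all.reshape(n * t, 4 * h)
        self.dWx[...] = x.reshape(n * t, f).T @ da2
        self.db[...] = da2.sum(axis=0)
        dx[...] = (da2 @ self.Wx.T).reshape(n, t, f)
        return dx


class Bidirectional(Layer):
    """Run two LSTMs over the sequence in opposite directions and
    concatenate their per-step outputs (N, T, 2H)."""

    def __init__(self, forward_lstm: LSTM, backward_lstm: LSTM):
        super().__init__()
        self.fw = forward_lstm
        self.bw = backward_lstm

    @property
    def params(self):
        return self.fw.params + self.bw.params

    @params.setter
    def params(self, value):
        pass

    @property
    def grads(self):
        return self.fw.grads + self.bw.grads

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x, train=False):
        yf = self.fw.forward(x, train=train)
        yb = self.bw.forward(x[:, ::-1], train=train)[:, ::-1]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy):
        h = self.fw.hidden
        dxf = self.fw.backward(dy[:, :, :h])
        dxb = self.bw.backward(np.ascontiguousarray(dy[:, ::-1, h:]))[:, ::-1]
        return dxf + dxb


class TemporalMeanPool(Layer):
    """(N, T, F) -> (N, F), averaging over time."""

    def forward(self, x, train=False):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._t, axis=1) / self._t
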
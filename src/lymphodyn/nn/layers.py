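"""Layers with forward/backward passes in plain numpy.

Shapes follow the channels-first convention: (batch, channels, *spatial).
Convolutions use stride 1 and "same" zero padding with odd kernels.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    """Same-padded stride-1 ND correlation.

    x: (B, C, *S); w: (F, C, *K); returns (out (B, F, *S), cols) where cols
    is the (B·P, C·prodK) patch matrix reused by the backward pass.
    """
    nd = w.ndim - 2
    spatial = x.shape[2:]
    pads = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in w.shape[2:]]
    xp = np.pad(x, pads)
    win = sliding_window_view(xp, w.shape[2:], axis=tuple(range(2, 2 + nd)))
    # win: (B, C, *S, *K) → (B, *S, C, *K) → (B·P, C·prodK)
    win = np.moveaxis(win, 1, 1 + nd)
    b_sz = x.shape[0]
    prod_s = int(np.prod(spatial))
    ck = w[0].size
    cols = win.reshape(b_sz * prod_s, ck)
    wmat = w.reshape(w.shape[0], ck)
    out = cols @ wmat.T
    if b is not None:
        out = out + b
    out = out.reshape(b_sz, *spatial, w.shape[0])
    out = np.moveaxis(out, -1, 1)
    return np.ascontiguousarray(out), cols


def conv_input_grad(grad_out: np.ndarray, w: np.ndarray, x_shape: tuple):
    """Gradient w.r.t. the conv input (also the LRP redistribution step)."""
    nd = w.ndim - 2
    spatial = x_shape[2:]
    b_sz = x_shape[0]
    prod_s = int(np.prod(spatial))
    gmat = np.moveaxis(grad_out, 1, -1).reshape(b_sz * prod_s, w.shape[0])
    gcols = gmat @ w.reshape(w.shape[0], -1)  # (B·P, C·prodK)
    gcols = gcols.reshape(b_sz, *spatial, x_shape[1], *w.shape[2:])
    gcols = np.moveaxis(gcols, 1 + nd, 1)  # (B, C, *S, *K)
    padded_shape = [b_sz, x_shape[1]] + [
        s + 2 * (k // 2) for s, k in zip(spatial, w.shape[2:])
    ]
    gxp = np.zeros(padded_shape)
    for kidx in itertools.product(*(range(k) for k in w.shape[2:])):
        sl = (slice(None), slice(None)) + tuple(
            slice(k, k + s) for k, s in zip(kidx, spatial)
        )
        gxp[sl] += gcols[(slice(None), slice(None)) + (slice(None),) * nd + kidx]
    crop = (slice(None), slice(None)) + tuple(
        slice(k // 2, k // 2 + s) for k, s in zip(w.shape[2:], spatial)
    )
    return gxp[crop]


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ConvND(Layer):
    """Stride-1 same-padded convolution over ``ndim`` spatial dims."""

    trainable = True

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, ndim: int, rng):
        self.ndim = ndim
        k = (kernel_size,) * ndim
        fan_in = in_channels * kernel_size**ndim
        scale = np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0, scale, size=(out_channels, in_channels, *k))
        self.b = np.zeros(out_channels)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, train=False):
        out, cols = conv_forward(x, self.w, self.b)
        self._cache = (x.shape, cols) if train else None
        return out

    def backward(self, grad):
        x_shape, cols = self._cache
        b_sz = x_shape[0]
        prod_s = int(np.prod(x_shape[2:]))
        gmat = np.moveaxis(grad, 1, -1).reshape(b_sz * prod_s, self.w.shape[0])
        self.gw = (gmat.T @ cols).reshape(self.w.shape)
        self.gb = gmat.sum(axis=0)
        return conv_input_grad(grad, self.w, x_shape)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPoolND(Layer):
    """Non-overlapping pooling of size 2 per spatial dim (floor crop)."""

    def __init__(self, ndim: int, size: int = 2):
        self.ndim = ndim
        self.size = size

    def _windows(self, x):
        s = self.size
        spatial = x.shape[2:]
        crop = tuple(slice(0, (d // s) * s) for d in spatial)
        xc = x[(slice(None), slice(None)) + crop]
        shape = [x.shape[0], x.shape[1]]
        for d in xc.shape[2:]:
            shape += [d // s, s]
        xr = xc.reshape(shape)
        # bring the window axes last: (B, C, *S_out, *win)
        win_axes = [3 + 2 * i for i in range(self.ndim)]
        order = [0, 1] + [2 + 2 * i for i in range(self.ndim)] + win_axes
        return xr.transpose(order), xc.shape

    def forward(self, x, train=False):
        xw, cropped_shape = self._windows(x)
        out = xw.max(axis=tuple(range(-self.ndim, 0)))
        self._cache = (x.shape, cropped_shape, xw, out)
        return out

    def backward(self, grad):
        x_shape, cropped_shape, xw, out = self._cache
        expand = out[(...,) + (None,) * self.ndim]
        mask = (xw == expand).astype(float)
        mask /= np.maximum(mask.sum(axis=tuple(range(-self.ndim, 0)), keepdims=True), 1)
        gw = mask * grad[(...,) + (None,) * self.ndim]
        # invert the transpose/reshape
        n = self.ndim
        inv_order = np.argsort([0, 1] + [2 + 2 * i for i in range(n)] + [3 + 2 * i for i in range(n)])
        gshape = [x_shape[0], x_shape[1]]
        for d in cropped_shape[2:]:
            gshape += [d // self.size, self.size]
        gx_cropped = gw.transpose(inv_order).reshape(cropped_shape)
        gx = np.zeros(x_shape)
        sl = (slice(None), slice(None)) + tuple(slice(0, d) for d in cropped_shape[2:])
        gx[sl] = gx_cropped
        return gx


class GlobalConcatPool(Layer):
    """Concatenated global max and average pooling → (B, 2C).

    An optional boolean mask (B, *spatial) restricts both pools to valid
    positions (used for zero-padded variable-length sequences).
    """

    def __init__(self):
        self.mask = None  # set externally per batch when needed

    def forward(self, x, train=False):
        b_sz, c = x.shape[:2]
        flat = x.reshape(b_sz, c, -1)
        if self.mask is not None:
            m = self.mask.reshape(b_sz, 1, -1).astype(bool)
            neg = np.where(m, flat, -np.inf)
            mx = neg.max(axis=2)
            cnt = np.maximum(m.sum(axis=2), 1)
            mean = np.where(m, flat, 0.0).sum(axis=2) / cnt
            self._cache = (x.shape, flat, m, cnt, mx)
        else:
            mx = flat.max(axis=2)
            mean = flat.mean(axis=2)
            self._cache = (x.shape, flat, None, flat.shape[2], mx)
        return np.concatenate([mx, mean], axis=1)

    def backward(self, grad):
        x_shape, flat, m, cnt, mx = self._cache
        b_sz, c = x_shape[:2]
        gmax, gmean = grad[:, :c], grad[:, c:]
        gflat = np.zeros_like(flat)
        if m is not None:
            is_max = (flat == mx[:, :, None]) & m
        else:
            is_max = flat == mx[:, :, None]
        ties = np.maximum(is_max.sum(axis=2, keepdims=True), 1)
        gflat += is_max * (gmax[:, :, None] / ties)
        if m is not None:
            gflat += m * (gmean[:, :, None] / np.asarray(cnt)[:, None, None])
        else:
            gflat += gmean[:, :, None] / cnt
        return gflat.reshape(x_shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_features: int, out_features: int, rng):
        scale = np.sqrt(2.0 / in_features)
        self.w = rng.normal(0, scale, size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class Dropout(Layer):
    def __init__(self, rate: float, rng):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask
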
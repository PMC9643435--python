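"""Layer-wise relevance propagation for :class:`Sequential` models.

Rule assignment: ε-rule on dense layers, z⁺-rule on convolutions,
winner-take-all through max pooling, proportional redistribution through
average pooling.  The propagated total is conserved (the sum of input
relevances approximates the explained logit).
"""

from __future__ import annotations

import numpy as np

from lymphodyn.nn.layers import (
    ConvND,
    Dense,
    Dropout,
    GlobalConcatPool,
    MaxPoolND,
    ReLU,
    conv_forward,
    conv_input_grad,
)


def _dense_epsilon(layer: Dense, x, relevance, eps):
    z = x @ layer.w + layer.b
    denom = z + eps * np.sign(z)
    denom = np.where(denom == 0, eps, denom)
    s = relevance / denom
    return x * (s @ layer.w.T)


def _conv_zplus(layer: ConvND, x, relevance, eps):
    xp = np.clip(x, 0, None)
    wp = np.clip(layer.w, 0, None)
    z, _ = conv_forward(xp, wp, None)
    s = relevance / (z + eps)
    c = conv_input_grad(s, wp, x.shape)
    return xp * c


def _maxpool_redistribute(layer: MaxPoolND, x, relevance):
    xw, cropped_shape = layer._windows(x)
    out = xw.max(axis=tuple(range(-layer.ndim, 0)))
    mask = (xw == out[(...,) + (None,) * layer.ndim]).astype(float)
    mask /= np.maximum(
        mask.sum(axis=tuple(range(-layer.ndim, 0)), keepdims=True), 1
    )
    rw = mask * relevance[(...,) + (None,) * layer.ndim]
    n = layer.ndim
    inv_order = np.argsort(
        [0, 1] + [2 + 2 * i for i in range(n)] + [3 + 2 * i for i in range(n)]
    )
    gshape = [x.shape[0], x.shape[1]]
    for d in cropped_shape[2:]:
        gshape += [d // layer.size, layer.size]
    r_cropped = rw.transpose(inv_order).reshape(cropped_shape)
    r = np.zeros(x.shape)
    sl = (slice(None), slice(None)) + tuple(slice(0, d) for d in cropped_shape[2:])
    r[sl] = r_cropped
    return r


def _globalpool_redistribute(layer: GlobalConcatPool, x, relevance, eps):
    b_sz, c = x.shape[:2]
    flat = x.reshape(b_sz, c, -1)
    rmax, rmean = relevance[:, :c], relevance[:, c:]
    if layer.mask is not None:
        m = layer.mask.reshape(b_sz, 1, -1).astype(bool)
    else:
        m = np.ones((b_sz, 1, flat.shape[2]), dtype=bool)
    neg = np.where(m, flat, -np.inf)
    mx = neg.max(axis=2, keepdims=True)
    is_max = (flat == mx) & m
    ties = np.maximum(is_max.sum(axis=2, keepdims=True), 1)
    r = is_max * (rmax[:, :, None] / ties)
    # average half: proportional to (non-negative) activation
    pos = np.where(m, np.clip(flat, 0, None), 0.0)
    denom = pos.sum(axis=2, keepdims=True)
    uniform = m / np.maximum(m.sum(axis=2, keepdims=True), 1)
    weights = np.where(denom > eps, pos / np.maximum(denom, eps), uniform)
    r = r + weights * rmean[:, :, None]
    return r.reshape(x.shape)


def lrp_explain(model, x: np.ndarray, target_class: int, eps: float = 1e-6) -> np.ndarray:
    """Relevance of every input element for the target-class logit.

    Returns an array shaped like ``x``.  Sum of relevances approximates
    the target logit (exact up to ε leakage and bias absorption).
    """
    activations = [np.asarray(x, dtype=float)]
    a = activations[0]
    for layer in model.layers:
        a = layer.forward(a, train=False)
        activations.append(a)
    logits = activations[-1]
    relevance = np.zeros_like(logits)
    relevance[:, target_class] = logits[:, target_class]
    for layer, inp in zip(reversed(model.layers), reversed(activations[:-1])):
        if isinstance(layer, Dense):
            relevance = _dense_epsilon(layer, inp, relevance, eps)
        elif isinstance(layer, ConvND):
            relevance = _conv_zplus(layer, inp, relevance, eps)
        elif isinstance(layer, MaxPoolND):
            relevance = _maxpool_redistribute(layer, inp, relevance)
        elif isinstance(layer, GlobalConcatPool):
            relevance = _globalpool_redistribute(layer, inp, relevance, eps)
        elif isinstance(layer, (ReLU, Dropout)):
            pass  # identity for relevance
        else:
            raise ValueError(
                f"unsupported layer type for relevance propagation: "
                f"{type(layer).__name__}"
            )
    return relevance
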
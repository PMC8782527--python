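"""Small neural-network primitives on numpy + autograd.

All parameters live in nested dicts of plain numpy arrays so that a whole
model can be flattened with :func:`autograd.misc.flatten` and optimized by
the numpy Adam loop in :mod:`djin.inference`.  Forward functions are written
with :mod:`autograd.numpy` and are therefore differentiable end to end,
including through the SDE solver and the GRU recursion.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

__all__ = [
    "elu",
    "softplus",
    "sigmoid",
    "mlp_init",
    "mlp_apply",
    "bank_init",
    "bank_apply",
    "gru_init",
    "gru_step",
]


def elu(x, alpha=1.0):
    """Exponential linear unit, the hidden activation used throughout."""
    return anp.where(x > 0, x, alpha * (anp.exp(anp.minimum(x, 0.0)) - 1.0))


def softplus(x):
    # overflow-safe: softplus(x) = max(x,0) + log1p(exp(-|x|))
    return anp.maximum(x, 0.0) + anp.log1p(anp.exp(-anp.abs(x)))


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def _dense_init(rng, d_in, d_out, scale=None):
    if scale is None:
        scale = 1.0 / np.sqrt(max(d_in, 1))
    return {
        "W": rng.normal(0.0, scale, size=(d_in, d_out)),
        "b": np.zeros(d_out),
    }


def mlp_init(sizes, rng, scale=None):
    """Initialize a feed-forward net with layer widths ``sizes``.

    ``sizes = [d_in, h1, ..., d_out]``.  Weights are Gaussian with sd
    1/sqrt(fan_in) unless ``scale`` overrides it; biases start at zero.
    """
    return [
        _dense_init(rng, sizes[i], sizes[i + 1], scale)
        for i in range(len(sizes) - 1)
    ]


def mlp_apply(params, x, act=elu, out_act=None):
    """Apply an MLP; hidden layers use ``act``, output uses ``out_act``."""
    h = x
    for layer in params[:-1]:
        h = act(anp.dot(h, layer["W"]) + layer["b"])
    last = params[-1]
    out = anp.dot(h, last["W"]) + last["b"]
    if out_act is not None:
        out = out_act(out)
    return out


def bank_init(n, sizes, rng, scale=None):
    """A bank of ``n`` independent MLPs of identical shape, stored stacked.

    Used for the per-variable drift nets f_i: one small network per health
    variable, evaluated for all variables at once via einsum.
    """
    layers = []
    for i in range(len(sizes) - 1):
        d_in, d_out = sizes[i], sizes[i + 1]
        s = scale if scale is not None else 1.0 / np.sqrt(max(d_in, 1))
        layers.append({
            "W": rng.normal(0.0, s, size=(n, d_in, d_out)),
            "b": np.zeros((n, d_out)),
        })
    return layers


def bank_apply(params, x, act=elu, out_act=None):
    """Apply the bank to ``x`` of shape (batch, n, d_in) -> (batch, n, d_out)."""
    h = x
    for layer in params[:-1]:
        h = act(anp.einsum("bnd,ndh->bnh", h, layer["W"]) + layer["b"])
    last = params[-1]
    out = anp.einsum("bnd,ndh->bnh", h, last["W"]) + last["b"]
    if out_act is not None:
        out = out_act(out)
    return out


def gru_init(d_in, hidden_sizes, rng, scale=None):
    """Stacked GRU cells; ``hidden_sizes`` e.g. (25, 10) for the hazard RNN."""
    cells = []
    prev = d_in
    for h in hidden_sizes:
        s = scale if scale is not None else 1.0 / np.sqrt(max(prev + h, 1))
        cells.append({
            # gates: reset, update, candidate — stacked along columns
            "Wx": rng.normal(0.0, s, size=(prev, 3 * h)),
            "Wh": rng.normal(0.0, s, size=(h, 3 * h)),
            "b": np.zeros(3 * h),
        })
        prev = h
    return cells


def _gru_cell(cell, x, h):
    nh = h.shape[-1]
    gx = anp.dot(x, cell["Wx"]) + cell["b"]
    gh = anp.dot(h, cell["Wh"])
    r = sigmoid(gx[..., :nh] + gh[..., :nh])
    z = sigmoid(gx[..., nh:2 * nh] + gh[..., nh:2 * nh])
    n = anp.tanh(gx[..., 2 * nh:] + r * gh[..., 2 * nh:])
    return (1.0 - z) * n + z * h


def gru_step(cells, x, hidden):
    """One step of the stacked GRU.

    ``hidden`` is a list of per-layer states (batch, h_l); returns the new
    list.  The top layer's state feeds the hazard head.
    """
    new_hidden = []
    inp = x
    for cell, h in zip(cells, hidden):
        h_new = _gru_cell(cell, inp, h)
        new_hidden.append(h_new)
        inp = h_new
    return new_hidden
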
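"""History-dependent mortality: recurrent hazard, survival curves, sampling.

The instantaneous mortality rate lambda(t) is computed by a 2-layer gated
recurrent unit (hidden sizes 25 and 10) that consumes the health state x(t)
step by step, so the hazard can depend on the history of health and not
just its current value.  The initial hidden state is produced by a small
feed-forward network H from (x0, u, t0).  The hazard head applies an
exponential link, so lambda >= 0 by construction, and

    S(t) = exp( - int_{t0}^{t} lambda(t') dt' )

with the integral computed by the trapezoid rule on the same fixed grid as
the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from ._nnops import gru_init, gru_step, mlp_apply, mlp_init
from .dynamics import scale_age

__all__ = [
    "SurvivalCurve",
    "init_hazard_params",
    "hazard_path",
    "survival_curve",
    "sample_death",
]

GRU_SIZES = (25, 10)


@dataclass
class SurvivalCurve:
    """Per-individual hazard path and survival function on a fixed grid."""

    times: np.ndarray     # ages, shape (T,) or (M, T)
    S: np.ndarray         # survival, same leading layout as lambda
    lam: np.ndarray       # hazard path

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        if np.any(S < -1e-9) or np.any(S > 1 + 1e-9):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(S, axis=-1) > 1e-9):
            raise ValueError("survival must be nonincreasing")


def init_hazard_params(n_vars, n_background, n_bg_mask, rng, *, init_hidden=30):
    """Initialize H (initial-state net), the stacked GRU and the hazard head.

    The head bias starts at log(0.01/yr) so initial hazards are small and
    the early survival likelihood is well-scaled.
    """
    d_init = n_vars + n_background + n_bg_mask + 1
    d_step = n_vars + 1                      # x(t) and the scaled age
    head_in = GRU_SIZES[-1]
    return {
        "H": mlp_init([d_init, init_hidden, sum(GRU_SIZES)], rng),
        "gru": gru_init(d_step, GRU_SIZES, rng),
        "head": mlp_init([head_in, 1], rng, scale=1e-2),
        "head_bias": np.array([np.log(0.01)]),
    }


def _initial_hidden(params, x0, u_ctx, t0):
    inp = anp.concatenate(
        [x0, u_ctx, scale_age(t0).reshape(-1, 1)], axis=1)
    h = anp.tanh(mlp_apply(params["H"], inp))
    return [h[:, :GRU_SIZES[0]], h[:, GRU_SIZES[0]:]]


def hazard_path(params, paths, u_ctx, t0, offsets):
    """Hazard lambda(t) >= 0 along trajectories.

    ``paths`` is (T, M, N) health states on the grid ``t0 + offsets``;
    returns lambda of shape (T, M).  The hidden state is initialized from
    (x(t0), u, t0) and advanced once per grid point consuming x(t).
    """
    T = paths.shape[0]
    if len(offsets) != T:
        raise ValueError("grid length does not match trajectory length")
    hidden = _initial_hidden(params, paths[0], u_ctx, t0)
    lams = []
    for j in range(T):
        age = t0 + offsets[j]
        inp = anp.concatenate(
            [paths[j], scale_age(age).reshape(-1, 1)], axis=1)
        hidden = gru_step(params["gru"], inp, hidden)
        raw = mlp_apply(params["head"], hidden[-1]) + params["head_bias"]
        lams.append(anp.exp(raw[:, 0]))
    return anp.stack(lams, axis=0)


def survival_curve(lambda_path, times):
    """S(t) = exp(-trapezoid cumulative integral of lambda); S(t0) = 1.

    ``lambda_path`` has time along axis 0 (shape (T,) or (T, M)); ``times``
    is the matching grid.  Negative hazards are an error.
    """
    lam = anp.atleast_1d(lambda_path)
    times = np.asarray(times, float)
    from autograd.tracer import getval
    if np.any(getval(lam) < 0):
        raise ValueError("hazard must be nonnegative")
    dt = np.diff(times)
    shape = dt.reshape((-1,) + (1,) * (lam.ndim - 1))
    inc = 0.5 * (lam[1:] + lam[:-1]) * shape
    cum = anp.cumsum(inc, axis=0)
    zero = anp.zeros((1,) + lam.shape[1:] if lam.ndim > 1 else (1,))
    return anp.exp(-anp.concatenate([zero, cum], axis=0))


def sample_death(lambda_path, dt, rng, *, t0=0.0, offsets=None):
    """Sample death times along hazard paths.

    Per step the individual survives with probability exp(-lambda(t) dt);
    the first failing step's midpoint is returned as the death age.  Input
    (T,) or (T, M); returns a scalar/array of death ages with NaN meaning
    alive at the end of the grid (censored at horizon).
    """
    lam = np.atleast_2d(np.asarray(lambda_path, float).T).T  # (T, M)
    T, M = lam.shape
    if offsets is None:
        offsets = np.arange(T) * dt
    rng = np.random.default_rng(rng)
    u = rng.random((T - 1, M))
    die = u > np.exp(-lam[:-1] * dt)
    death = np.full(M, np.nan)
    t0 = np.broadcast_to(np.asarray(t0, float), (M,))
    for m in range(M):
        hits = np.where(die[:, m])[0]
        if hits.size:
            death[m] = t0[m] + offsets[hits[0]] + dt / 2.0
    if np.isscalar(lambda_path[0]) or np.asarray(lambda_path).ndim == 1:
        return float(death[0])
    return death
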
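"""Health-state SDE: drift/diffusion functions and the stochastic integrator.

The health state x(t) of each individual follows

    dx_i = ( sum_j W_ij x_j + f_i(x_i, u, t) ) dt + sigma_x,i(x) dB_i(t),

where W is a constant directed interaction matrix with zero diagonal (the
interpretable network), the f_i are small per-variable neural networks
capturing single-variable trends (the "diagonal" of the interaction matrix),
and sigma_x is a diagonal state-dependent diffusion parameterized by a
neural network.  The variational posterior over trajectories is a second SDE
whose drift adds a small correction network g and replaces the sampled W
with its posterior mean.

Integration uses an explicit derivative-free strong-order-1.0 stochastic
Runge-Kutta scheme for diagonal noise on a fixed grid (default step 0.5
years), and is differentiable end to end with autograd (the Brownian
increments are pre-generated constants, so gradients are pathwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

from ._nnops import bank_apply, bank_init, mlp_apply, mlp_init, softplus

__all__ = [
    "TrajectoryEnsemble",
    "init_dynamics_params",
    "init_latent_drift_params",
    "scale_age",
    "prior_drift",
    "posterior_drift",
    "latent_drift",
    "diffusion",
    "make_grid",
    "integrate",
]

# ages enter every network on a standardized scale
AGE_CENTER = 70.0
AGE_SCALE = 15.0

SIGMA_FLOOR = 1e-3


def scale_age(t):
    return (t - AGE_CENTER) / AGE_SCALE


@dataclass
class TrajectoryEnsemble:
    """Sampled paths on a fixed grid.

    ``offsets`` are years from baseline (length T, spacing dt); per-path
    ages are ``t0[m] + offsets``.  ``paths`` has shape (S, T, M, N) and
    ``dW`` the Brownian increments (S, T-1, M, N) used to generate them.
    """

    offsets: np.ndarray
    t0: np.ndarray
    paths: np.ndarray
    dW: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.offsets[1] - self.offsets[0])

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]

    def ages(self) -> np.ndarray:
        """Per-individual age grid, shape (M, T)."""
        return self.t0[:, None] + self.offsets[None, :]


# ---------------------------------------------------------------------------
# Parameters


def init_dynamics_params(n_vars, n_background, n_bg_mask, rng, *,
                         f_hidden=12, g_hidden=8):
    """Initialize W, the f_i bank, the posterior correction g and sigma_x.

    W starts at zero here; the variational state in :mod:`djin.inference`
    owns its posterior location/scale.  sigma_x's output bias is set so the
    initial diffusion is a small positive value (~0.1) for stable training.
    """
    d_f = 2 + n_background + n_bg_mask          # (x_i, age, u, u_mask)
    d_g = n_vars + 1 + n_background + n_bg_mask  # (x, age, u, u_mask)
    sigma = mlp_init([n_vars, n_vars, n_vars], rng)
    sigma[-1]["b"] = np.full(n_vars, np.log(np.expm1(0.1)))
    f_bank = bank_init(n_vars, [d_f, f_hidden, 1], rng)
    f_bank[-1]["W"] = np.zeros_like(f_bank[-1]["W"])  # zero drift at init
    return {
        "W": np.zeros((n_vars, n_vars)),
        "f": f_bank,
        "g": mlp_init([d_g, g_hidden, n_vars], rng, scale=1e-2),
        "sigma": sigma,
    }


def init_latent_drift_params(latent_dim, n_background, n_bg_mask, rng, *,
                             hidden=12, include_background=True):
    """Full feed-forward drift for the latent-space model variant.

    With ``include_background=False`` (the 1D-summary variant) the drift
    sees only (z, age); all background information must then travel through
    the encoder into the latent state itself.
    """
    d_in = latent_dim + 1 + (n_background + n_bg_mask if include_background else 0)
    sigma = mlp_init([latent_dim, latent_dim, latent_dim], rng)
    sigma[-1]["b"] = np.full(latent_dim, np.log(np.expm1(0.1)))
    return {
        "net": mlp_init([d_in, hidden, latent_dim], rng),
        "sigma": sigma,
    }


# ---------------------------------------------------------------------------
# Drift / diffusion


def _f_bank(f_params, x, age, u_ctx):
    """Evaluate all f_i at once: x (M, N), age (M,), u_ctx (M, C) -> (M, N)."""
    M, N = x.shape[0], x.shape[1]
    a = anp.broadcast_to(scale_age(age).reshape(-1, 1, 1), (M, N, 1))
    xi = x[:, :, None]
    uc = anp.broadcast_to(u_ctx[:, None, :], (M, N, u_ctx.shape[1]))
    inp = anp.concatenate([xi, a, uc], axis=2)
    return bank_apply(f_params, inp)[:, :, 0]


def prior_drift(x, u_ctx, age, W, f_params):
    """Network drift: W x + f(x, u, t); W's diagonal is excluded (f owns it)."""
    W = W * (1.0 - anp.eye(W.shape[0]))
    return anp.dot(x, W.T) + _f_bank(f_params, x, age, u_ctx)


def posterior_drift(x, u_ctx, age, W_bar, f_params, g_params):
    """Variational drift: W̄ x + f(x, u, t) + g(x, u, t)."""
    g_in = anp.concatenate(
        [x, scale_age(age).reshape(-1, 1) * anp.ones((x.shape[0], 1)), u_ctx],
        axis=1)
    g = mlp_apply(g_params, g_in)
    return prior_drift(x, u_ctx, age, W_bar, f_params) + g


def latent_drift(z, u_ctx, age, params, include_background=True):
    """Feed-forward drift of the latent-space variant (no W).

    The 1D-summary variant passes ``include_background=False`` so the
    drift sees only (z, age) and background information must flow through
    the encoder into z itself.
    """
    a = scale_age(age).reshape(-1, 1) * anp.ones((z.shape[0], 1))
    if include_background:
        inp = anp.concatenate([z, a, u_ctx], axis=1)
    else:
        inp = anp.concatenate([z, a], axis=1)
    return mlp_apply(params["net"], inp)


def diffusion(sigma_params, x):
    """Diagonal diffusion sigma_x(x) >= SIGMA_FLOOR, via a softplus link."""
    return softplus(mlp_apply(sigma_params, x)) + SIGMA_FLOOR


# ---------------------------------------------------------------------------
# Integrator


def make_grid(horizon, dt):
    """Years-from-baseline grid [0, horizon] inclusive with constant step."""
    n = int(round(horizon / dt))
    return np.arange(n + 1) * dt


def integrate(drift, diff, x0, t0, horizon, dt, n_paths=1, rng=None,
              dW=None) -> TrajectoryEnsemble:
    """Integrate the SDE with a derivative-free strong-order-1.0 SRK scheme.

    ``drift(x, age)`` and ``diff(x)`` map (M, N) arrays to (M, N) arrays;
    ``x0`` is (M, N) and ``t0`` (M,) the baseline ages.  One step combines
    a Heun (2-stage) drift with a derivative-free Milstein diffusion
    correction built on the supporting value xb:

        xb    = x + mu dt + sig sqrt(dt)
        x_new = x + (mu + drift(x + mu dt, t + dt)) dt / 2 + sig dW
                + (sig(xb) - sig(x)) (dW^2 - dt) / (2 sqrt(dt))

    For diagonal noise this attains strong order 1.0, and deterministic
    order 2 in the zero-noise limit.  Brownian increments can be supplied
    via ``dW`` (S, T-1, M, N) for coupling tests; otherwise they are drawn
    from ``rng``.  Differentiable with autograd.
    """
    offsets = make_grid(horizon, dt)
    T = len(offsets)
    x0 = anp.atleast_2d(x0)
    M, N = getval(x0).shape
    t0 = np.broadcast_to(np.asarray(t0, float), (M,))
    if dW is None:
        rng = np.random.default_rng(rng)
        dW = rng.normal(0.0, np.sqrt(dt), size=(n_paths, T - 1, M, N))
    else:
        dW = np.asarray(dW)
        n_paths = dW.shape[0]
    sqdt = np.sqrt(dt)
    all_paths = []
    for s in range(n_paths):
        x = x0
        states = [x]
        for j in range(T - 1):
            age = t0 + offsets[j]
            mu = drift(x, age)
            sig = diff(x)
            dw = dW[s, j]
            xb = x + mu * dt + sig * sqdt
            sig_b = diff(xb)
            mu2 = drift(x + mu * dt, age + dt)
            x = x + 0.5 * (mu + mu2) * dt + sig * dw \
                + (sig_b - sig) * (dw * dw - dt) / (2.0 * sqdt)
            if not np.all(np.isfinite(getval(x))):
                bad = np.where(~np.all(np.isfinite(getval(x)), axis=1))[0]
                raise FloatingPointError(
                    f"non-finite state at step {j + 1} (path {s}, "
                    f"individuals {bad[:5].tolist()}); "
                    "reduce dt or the drift weights")
            states.append(x)
        all_paths.append(anp.stack(states, axis=0))
    paths = anp.stack(all_paths, axis=0)
    return TrajectoryEnsemble(offsets=offsets, t0=t0, paths=paths, dW=dW)
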
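"""Flow-based VAE for baseline health states.

Missing baseline variables are imputed by encoding the available baseline
information (values, observation mask, background covariates, baseline age)
into a 20-dimensional latent distribution, enriching that distribution with
conditional RealNVP coupling flows, and decoding latent samples into a
complete baseline state.  Observed coordinates are always kept:

    x0 = o .* y0 + (1 - o) .* x~0,   x~0 ~ N(mu_x(z, u, t0), sigma_y^2).

The same decoder generates synthetic baselines from the standard-normal
latent prior when no health measurements are available at all.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

from ._nnops import mlp_apply, mlp_init
from .dynamics import scale_age

__all__ = [
    "init_imputer_params",
    "latent_dim_of",
    "encode",
    "flow_push",
    "flow_inverse",
    "decode",
    "sample_posterior",
    "impute",
    "generate_baseline",
]

LATENT_DIM = 20
GAMMA_DIM = 10


def init_imputer_params(n_vars, n_background, n_bg_mask, rng, *,
                        latent_dim=LATENT_DIM, gamma_dim=GAMMA_DIM,
                        flow_hidden=(30, 24, 10)):
    """Initialize encoder, decoder and the conditional coupling flows.

    Encoder: (y~0, o0, u, u_mask, t0) -> hidden 95, 70 -> 2*latent output
    split into mu_z and raw log sigma_z, plus a separate gamma_z head of
    size ``gamma_dim`` off the last hidden layer.  Decoder: (z, u, u_mask,
    t0) -> hidden 65 -> N.  Coupling masks alternate even/odd coordinates
    with the layer index; flows start at the identity (zero final layer) so
    training begins from a plain Gaussian posterior.
    """
    d_enc = 2 * n_vars + n_background + n_bg_mask + 1
    d_dec = latent_dim + n_background + n_bg_mask + 1
    flows = []
    for layer, h in enumerate(flow_hidden):
        d_a = int(np.sum(np.arange(latent_dim) % 2 == layer % 2))
        d_b = latent_dim - d_a
        net = mlp_init([d_a + gamma_dim, h, 2 * d_b], rng)
        net[-1]["W"] = np.zeros_like(net[-1]["W"])   # identity start
        flows.append(net)
    return {
        "enc_hidden": mlp_init([d_enc, 95, 70], rng),
        "enc_out": mlp_init([70, 2 * latent_dim], rng, scale=1e-2),
        "enc_gamma": mlp_init([70, gamma_dim], rng, scale=1e-2),
        "dec": mlp_init([d_dec, 65, n_vars], rng),
        "flows": flows,
    }


def latent_dim_of(params) -> int:
    return params["enc_out"][-1]["b"].shape[0] // 2


def encode(params, y_tilde, o0, u_ctx, t0):
    """Map filled baseline inputs to (mu_z, sigma_z, gamma_z).

    ``y_tilde`` must have missing entries pre-filled (population fill /
    corruption); NaNs are an error.  sigma_z uses an exponential link on
    half the raw output, clamped to [1e-6, 1e3].
    """
    if not np.all(np.isfinite(getval(y_tilde))):
        raise ValueError("encoder input contains NaN; fill must precede encoding")
    d = latent_dim_of(params)
    inp = anp.concatenate(
        [y_tilde, o0, u_ctx, scale_age(t0).reshape(-1, 1)], axis=1)
    h = mlp_apply(params["enc_hidden"], inp)
    h = anp.where(h > 0, h, anp.exp(anp.minimum(h, 0.0)) - 1.0)  # ELU on top
    out = mlp_apply(params["enc_out"], h)
    mu_z = out[:, :d]
    sigma_z = anp.clip(anp.exp(0.5 * out[:, d:]), 1e-6, 1e3)
    gamma_z = mlp_apply(params["enc_gamma"], h)
    return mu_z, sigma_z, gamma_z


def _coupling(net, layer, d, z, gamma_z, inverse=False):
    a_sel = np.arange(d) % 2 == layer % 2
    b_sel = ~a_sel
    za = z[:, a_sel]
    zb = z[:, b_sel]
    out = mlp_apply(net, anp.concatenate([za, gamma_z], axis=1), act=anp.tanh)
    nb = int(b_sel.sum())
    s = anp.tanh(out[:, :nb])
    t = out[:, nb:]
    if inverse:
        zb_new = (zb - t) * anp.exp(-s)
        log_det = -anp.sum(s, axis=1)
    else:
        zb_new = zb * anp.exp(s) + t
        log_det = anp.sum(s, axis=1)
    cols = []
    ia = ib = 0
    for j in range(d):
        if a_sel[j]:
            cols.append(za[:, ia]); ia += 1
        else:
            cols.append(zb_new[:, ib]); ib += 1
    return anp.stack(cols, axis=1), log_det


def flow_push(params, z0, gamma_z):
    """Apply the coupling layers; returns (z, summed log|det Jacobian|)."""
    d = latent_dim_of(params)
    z = z0
    log_det = anp.zeros(z0.shape[0])
    for layer, net in enumerate(params["flows"]):
        z, ld = _coupling(net, layer, d, z, gamma_z)
        log_det = log_det + ld
    return z, log_det


def flow_inverse(params, z, gamma_z):
    """Exact inverse of :func:`flow_push`."""
    d = latent_dim_of(params)
    out = z
    for layer in range(len(params["flows"]) - 1, -1, -1):
        out, _ = _coupling(params["flows"][layer], layer, d, out, gamma_z,
                           inverse=True)
    return out


def decode(params, z, u_ctx, t0):
    """Decode a latent sample to the N-dim mean of the baseline Gaussian."""
    inp = anp.concatenate(
        [z, u_ctx, scale_age(t0).reshape(-1, 1)], axis=1)
    return mlp_apply(params["dec"], inp)


def sample_posterior(params, y_tilde, o0, u_ctx, t0, rng=None, eps=None):
    """One reparameterized latent draw z ~ q(z | inputs) with its log-det."""
    mu_z, sigma_z, gamma_z = encode(params, y_tilde, o0, u_ctx, t0)
    if eps is None:
        rng = np.random.default_rng(rng)
        eps = rng.standard_normal(getval(mu_z).shape)
    z0 = mu_z + sigma_z * eps
    z, log_det = flow_push(params, z0, gamma_z)
    return z, log_det, (mu_z, sigma_z, gamma_z)


def impute(params, y0, o0, u_ctx, t0, sigma_y, n_samples, rng,
           pop_mean=None, pop_sd=None):
    """Multiple imputation of the baseline state.

    Missing encoder inputs are temporarily filled with stratified population
    draws (``pop_mean``/``pop_sd``; zero/unit on the transformed scale when
    not supplied).  Returns an array (n_samples, M, N); observed coordinates
    are identical to ``y0`` in every sample.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng)
    y0 = np.asarray(y0, float)
    o0 = np.asarray(o0, float)
    M, N = y0.shape
    if pop_mean is None:
        pop_mean = np.zeros((M, N))
    if pop_sd is None:
        pop_sd = np.ones((M, N))
    out = []
    for _ in range(n_samples):
        fill = rng.normal(pop_mean, pop_sd)
        y_tilde = o0 * y0 + (1.0 - o0) * fill
        z, _, _ = sample_posterior(params, y_tilde, o0, u_ctx, t0, rng=rng)
        mu_x = decode(params, z, u_ctx, t0)
        x_tilde = getval(mu_x) + rng.normal(0.0, 1.0, (M, N)) * sigma_y
        out.append(o0 * y0 + (1.0 - o0) * x_tilde)
    return np.stack(out, axis=0)


def generate_baseline(params, u_ctx, t0, sigma_y, n_samples, rng,
                      pop_mean=None, pop_sd=None):
    """Sample synthetic baseline states from the latent prior.

    z0 ~ N(0, I) is pushed through the flows conditioned on gamma_z from
    encoding population-filled inputs with an all-zero observation mask,
    then decoded; the observation-model noise sigma_y is added.  Returns
    (n_samples, M, N); n_samples = 0 yields an empty array.
    """
    rng = np.random.default_rng(rng)
    u_ctx = np.atleast_2d(u_ctx)
    M = u_ctx.shape[0]
    d = latent_dim_of(params)
    n_vars = params["dec"][-1]["b"].shape[0]
    if n_samples == 0:
        return np.empty((0, M, n_vars))
    if pop_mean is None:
        pop_mean = np.zeros((M, n_vars))
    if pop_sd is None:
        pop_sd = np.ones((M, n_vars))
    o0 = np.zeros((M, n_vars))
    out = []
    for _ in range(n_samples):
        y_tilde = rng.normal(pop_mean, pop_sd)
        _, _, gamma_z = encode(params, y_tilde, o0, u_ctx, t0)
        z0 = rng.standard_normal((M, d))
        z, _ = flow_push(params, z0, gamma_z)
        mu_x = decode(params, z, u_ctx, t0)
        out.append(getval(mu_x) + rng.normal(0.0, 1.0, (M, n_vars)) * sigma_y)
    return np.stack(out, axis=0)
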
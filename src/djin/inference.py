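"""Variational objective and training loop.

The model is fitted by maximizing an evidence lower bound that combines,
per individual (weighted by its replication weight s):

* a masked Gaussian log-likelihood of the observed health values at every
  visit against the latent trajectory x(t) (the baseline visit is scored
  against the decoder mean, which provides the self-supervised
  reconstruction signal for artificially corrupted entries);
* the survival log-likelihood of the (death age, censoring) outcome under
  the recurrent hazard, including an integral of log(1 - S) over a window
  past the death age that pushes S toward 0 after observed deaths;
* a path penalty -1/2 int ||sigma_x^-1 (W x - W_bar x - g)||^2 dt — the
  Girsanov KL between the posterior SDE (drift W_bar x + f + g) and the
  network SDE (drift W x + f, with W sampled from its Laplace posterior);
* the latent-space KL of the flow posterior against N(0, I);

minus global KL terms for the Laplace edge posteriors against
Laplace(0, 0.05) and the Gamma measurement-noise posteriors against
Gamma(1, 25000).  KL terms are annealed: trajectory/latent terms ramp
linearly over the first anneal window, the parameter priors over the
second.  Optimization is Adam with plateau-triggered learning-rate decay
and best-validation checkpointing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Callable

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten
from autograd.scipy.special import gammaln, psi
from autograd.tracer import getval

from . import dataio, dynamics, imputer, mortality
from .dataio import CohortDataset, PopulationStats

__all__ = [
    "TrainConfig",
    "VariationalState",
    "init_state",
    "obs_loglik",
    "survival_loglik",
    "path_penalty",
    "kl_laplace",
    "kl_gamma",
    "kl_latent",
    "anneal",
    "elbo",
    "train",
]

LOG2PI = np.log(2.0 * np.pi)
S_EPS = 1e-6


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the published schedule."""

    epochs: int = 500
    batch_size: int = 1000
    lr: float = 1e-2
    plateau_factor: float = 0.5
    plateau_patience: int = 40
    anneal_xz: tuple = (0, 300)
    anneal_W: tuple = (300, 500)
    dt: float = 0.5
    horizon: float = 20.0
    a_max_window: float = 5.0
    keep_prob: float = 0.9
    latent_dim: int = 20
    gamma_dim: int = 10
    flow_hidden: tuple = (30, 24, 10)
    prior_w_scale: float = 0.05
    # shape-rate; an exponential prior on sigma_y with scale 25000 —
    # weakly informative on the z-scored measurement scale
    prior_gamma: tuple = (1.0, 1.0 / 25000.0)
    mode: str = "network"          # "network" | "latent" | "latent_summary"
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr", "dt", "horizon",
                     "a_max_window", "keep_prob", "latent_dim"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be nonnegative")
        if not (self.anneal_xz[0] <= self.anneal_xz[1] <= self.anneal_W[0]
                <= self.anneal_W[1]):
            raise ValueError("anneal windows must be ordered")


@dataclass
class VariationalState:
    """All point parameters theta and variational parameters phi.

    ``params`` is a nested dict of numpy arrays: Laplace posterior location
    W_bar and log-scale for every directed edge, Gamma posterior log-shape
    and log-rate per measurement-noise parameter, and point estimates for
    the drift, diffusion, correction, encoder/decoder/flow and hazard
    networks.
    """

    params: dict
    config: TrainConfig
    n_vars: int
    n_background: int
    schema: dataio.VariableSchema | None = None
    pop_stats: PopulationStats | None = None
    history: list = field(default_factory=list)

    # posterior views ----------------------------------------------------
    @property
    def W_bar(self) -> np.ndarray:
        W = self.params["W_bar"]
        return W * (1.0 - np.eye(W.shape[0]))

    @property
    def b(self) -> np.ndarray:
        return np.exp(self.params["log_b"])

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(self.params["log_alpha"])

    @property
    def beta(self) -> np.ndarray:
        return np.exp(self.params["log_beta"])

    @property
    def sigma_y(self) -> np.ndarray:
        """Posterior-mean measurement noise scale per variable."""
        return self.alpha / self.beta

    def save(self, path):
        flat, _ = flatten(self.params)
        np.savez(
            path, flat=flat, n_vars=self.n_vars,
            n_background=self.n_background,
            config=np.array(repr(asdict(self.config)), dtype=object))

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=True) as d:
            cfg = TrainConfig(**eval(str(d["config"])))
            state = init_state(int(d["n_vars"]), int(d["n_background"]),
                               cfg, np.random.default_rng(0))
            _, unflat = flatten(state.params)
            state.params = unflat(d["flat"])
        return state


def init_state(n_vars, n_background, config: TrainConfig, rng,
               schema=None, pop_stats=None) -> VariationalState:
    """Initialize near the priors: W_bar ~ N(0, 0.01^2), b = 0.05,
    near-identity flows, small positive diffusion."""
    rng = np.random.default_rng(rng)
    nb = n_background           # background mask appended in full
    params = {
        "W_bar": rng.normal(0.0, 0.01, (n_vars, n_vars)),
        "log_b": np.full((n_vars, n_vars), np.log(0.05)),
        "log_alpha": np.full(n_vars, np.log(25.0)),
        "log_beta": np.full(n_vars, np.log(250.0)),
        "dyn": dynamics.init_dynamics_params(n_vars, n_background, nb, rng),
        "imp": imputer.init_imputer_params(
            n_vars, n_background, nb, rng, latent_dim=config.latent_dim,
            gamma_dim=config.gamma_dim, flow_hidden=config.flow_hidden),
    }
    if config.mode == "network":
        params["haz"] = mortality.init_hazard_params(n_vars, n_background, nb, rng)
    else:
        include_bg = config.mode != "latent_summary"
        params["lat_f"] = dynamics.init_latent_drift_params(
            config.latent_dim, n_background, nb, rng,
            include_background=include_bg)
        d_g = config.latent_dim + 1 + (n_background + nb if include_bg else 0)
        from ._nnops import mlp_init
        params["lat_g"] = mlp_init([d_g, 8, config.latent_dim], rng, scale=1e-2)
        params["haz"] = mortality.init_hazard_params(
            config.latent_dim, n_background, nb, rng)
    return VariationalState(params=params, config=config, n_vars=n_vars,
                            n_background=n_background, schema=schema,
                            pop_stats=pop_stats)


# ---------------------------------------------------------------------------
# Likelihood pieces (standalone, per-individual forms used in tests/docs)


def obs_loglik(y, o, x, sigma_y):
    """Masked Gaussian log-density summed over observed entries.

    All arguments broadcast; unobserved entries (o = 0) contribute exactly
    zero regardless of their y content.
    """
    sigma_y = anp.asarray(sigma_y)
    if np.any(getval(sigma_y) <= 0):
        raise ValueError("sigma_y must be positive")
    z = (anp.asarray(y) - x) / sigma_y
    ll = -0.5 * z ** 2 - anp.log(sigma_y) - 0.5 * LOG2PI
    return anp.sum(anp.asarray(o) * ll)


def _trap_weights(idx, T, dt):
    """Composite-trapezoid weights from grid point 0 to grid point idx.

    Returns (T, M); all-zero columns where idx = 0.
    """
    idx = np.asarray(idx, int)[None, :]
    j = np.arange(T)[:, None]
    inner = (j >= 1) & (j <= idx - 1)
    edge = (j == 0) | (j == idx)
    return np.where(idx >= 1, inner * dt + edge * (dt / 2.0), 0.0)


def _window_weights(lo, hi, T, dt):
    """Trapezoid weights on [lo, hi] grid indices; zero when hi <= lo."""
    lo = np.asarray(lo, int)[None, :]
    hi = np.asarray(hi, int)[None, :]
    j = np.arange(T)[:, None]
    inner = (j >= lo + 1) & (j <= hi - 1)
    edge = (j == lo) | (j == hi)
    return np.where(hi > lo, inner * dt + edge * (dt / 2.0), 0.0)


def survival_loglik(S, lam, times, a, c, a_max_window=5.0):
    """Survival log-likelihood of one individual on its grid.

    Uncensored (c=0): log lambda(a) + log S(a) + int_a^{a+window}
    log(1 - S) dt.  Censored (c=1): int_{t0}^{a} log S dt.  Integrals use
    the trapezoid rule on the model grid; S is clamped to
    [1e-6, 1 - 1e-6] before logs.
    """
    times = np.asarray(times, float)
    dt = times[1] - times[0]
    T = len(times)
    ia = int(np.clip(round((a - times[0]) / dt), 0, T - 1))
    Sc = anp.clip(S, S_EPS, 1.0 - S_EPS)
    if c:
        w = _trap_weights(np.array([ia]), T, dt)[:, 0]
        return anp.sum(w * anp.log(Sc))
    ie = int(np.clip(round((a + a_max_window - times[0]) / dt), ia, T - 1))
    w = _window_weights(np.array([ia]), np.array([ie]), T, dt)[:, 0]
    return anp.log(lam[ia]) + anp.log(Sc[ia]) \
        + anp.sum(w * anp.log(1.0 - Sc))


def path_penalty(paths, times, W_sample, W_bar, g_values, sigma_x):
    """Girsanov path penalty for one trajectory.

    ``paths`` (T, N) on grid ``times``; ``g_values`` (T, N) is the
    correction drift along the path and ``sigma_x`` (T, N) the diffusion.
    Returns -1/2 int ||sigma_x^-1 ((W - W_bar) x - g)||^2 dt <= 0.
    """
    if np.any(np.asarray(getval(sigma_x)) <= 0):
        raise ValueError("sigma_x must be positive")
    times = np.asarray(times, float)
    dt = times[1] - times[0]
    T = len(times)
    dW = (W_sample - W_bar) * (1.0 - anp.eye(W_sample.shape[0]))
    mism = anp.dot(paths, dW.T) - g_values
    integrand = anp.sum((mism / sigma_x) ** 2, axis=1)
    w = _trap_weights(np.array([T - 1]), T, dt)[:, 0]
    return -0.5 * anp.sum(w * integrand)


# ---------------------------------------------------------------------------
# KL terms


def kl_laplace(m, b, prior_scale=0.05):
    """Closed-form KL( Laplace(m, b) || Laplace(0, s) ), summed.

    KL = log(s/b) + |m|/s + (b/s) exp(-|m|/b) - 1.
    """
    if np.any(np.asarray(getval(b)) <= 0):
        raise ValueError("Laplace scale must be positive")
    s = prior_scale
    return anp.sum(anp.log(s / b) + anp.abs(m) / s
                   + (b / s) * anp.exp(-anp.abs(m) / b) - 1.0)


def kl_gamma(alpha, beta, prior=(1.0, 1.0 / 25000.0)):
    """Closed-form KL( Gamma(a, b) || Gamma(a0, b0) ), summed.

    Shape/rate parameterization throughout:
    KL = (a - a0) psi(a) - ln G(a) + ln G(a0) + a0 (ln b - ln b0)
         + a (b0 - b) / b.
    The default prior is the measurement-noise prior, an exponential with
    scale 25000 (shape 1, rate 4e-5).
    """
    a0, b0 = prior
    if np.any(np.asarray(getval(alpha)) <= 0) \
            or np.any(np.asarray(getval(beta)) <= 0):
        raise ValueError("Gamma parameters must be positive")
    return anp.sum((alpha - a0) * psi(alpha) - gammaln(alpha) + gammaln(a0)
                   + a0 * (anp.log(beta) - np.log(b0))
                   + alpha * (b0 - beta) / beta)


def kl_latent(mu_z, sigma_z, log_det):
    """Per-individual latent KL: Gaussian-vs-N(0,I) KL minus flow log-det."""
    if np.any(np.asarray(getval(sigma_z)) <= 0):
        raise ValueError("sigma_z must be positive")
    gauss = 0.5 * anp.sum(mu_z ** 2 + sigma_z ** 2 - 1.0
                          - 2.0 * anp.log(sigma_z), axis=-1)
    return gauss - log_det


def anneal(epoch, config: TrainConfig):
    """KL annealing factors (beta_xz, beta_W) at a given epoch."""
    lo, hi = config.anneal_xz
    beta_xz = np.clip((epoch - lo) / max(hi - lo, 1), 0.0, 1.0)
    lo, hi = config.anneal_W
    beta_W = np.clip((epoch - lo) / max(hi - lo, 1), 0.0, 1.0)
    return float(beta_xz), float(beta_W)


# ---------------------------------------------------------------------------
# Batched ELBO


def prepare_batch(cohort: CohortDataset, config: TrainConfig) -> dict:
    """Precompute the numpy constants of the batched objective.

    Visit ages are snapped to the nearest grid point; the death/censoring
    age to index ``ia`` (clipped to the grid).  Trapezoid weight matrices
    encode the per-individual integration limits.
    """
    dt, horizon = config.dt, config.horizon
    offsets = dynamics.make_grid(horizon, dt)
    T = len(offsets)
    M = cohort.n_individuals
    t0 = cohort.t0
    k_idx = np.clip(np.round((cohort.times - t0[:, None]) / dt), 0, T - 1)
    k_idx = np.nan_to_num(k_idx).astype(int)
    valid = cohort.visit_mask.astype(bool) \
        & (cohort.times - t0[:, None] <= horizon + 1e-9)
    ia = np.clip(np.round((cohort.a - t0) / dt), 0, T - 1).astype(int)
    ie = np.clip(ia + int(round(config.a_max_window / dt)), ia, T - 1)
    u_ctx = np.concatenate([cohort.u, cohort.u_mask], axis=1)
    return {
        "offsets": offsets, "T": T, "M": M, "t0": t0,
        "y": cohort.y, "o": cohort.o * valid[:, :, None],
        "k_idx": k_idx, "valid": valid.astype(float),
        "ia": ia, "c": cohort.c.astype(float), "s": cohort.s,
        "u_ctx": u_ctx,
        "y0": cohort.y0, "o0": cohort.o0,
        "cens_w": _trap_weights(ia, T, dt),
        "dead_w": _window_weights(ia, ie, T, dt),
        "pen_w": _trap_weights(np.full(M, T - 1), T, dt),
        # encoder inputs; overwritten by the corruption step each epoch
        "y_enc": cohort.y0.copy(), "o_enc": cohort.o0.copy(),
    }


def sample_noise(batch, config: TrainConfig, rng) -> dict:
    """Draw every stochastic input of one ELBO evaluation up front."""
    rng = np.random.default_rng(rng)
    M, T = batch["M"], batch["T"]
    d = config.latent_dim
    n_vars = batch["y"].shape[2]
    n_state = n_vars if config.mode == "network" else d
    return {
        "eps_z": rng.standard_normal((M, d)),
        "eps_x0": rng.standard_normal((M, n_vars)),
        "dW": rng.normal(0.0, np.sqrt(config.dt), (1, T - 1, M, n_state)),
        "U_w": rng.uniform(-0.5 + 1e-12, 0.5 - 1e-12, (n_vars, n_vars)),
    }


def _gather(arr, idx):
    """arr (T, M, ...) -> (M, ...) taking time index idx[m] for row m."""
    return arr[idx, np.arange(len(idx))]


def elbo_loss(params, batch, noise, betas, config: TrainConfig,
              kl_scale=1.0):
    """Negative weighted-mean ELBO of one batch (the training loss)."""
    beta_xz, beta_W = betas
    dt = config.dt
    T, M = batch["T"], batch["M"]
    u_ctx, t0 = batch["u_ctx"], batch["t0"]
    sigma_y = anp.exp(params["log_alpha"] - params["log_beta"])

    # -- baseline imputation (steps 2-3) --
    z, log_det, (mu_z, sigma_z, _) = imputer.sample_posterior(
        params["imp"], batch["y_enc"], batch["o_enc"], u_ctx, t0,
        eps=noise["eps_z"])

    if config.mode == "network":
        mu_x = imputer.decode(params["imp"], z, u_ctx, t0)
        x_tilde = mu_x + sigma_y * noise["eps_x0"]
        x0 = batch["o0"] * batch["y0"] + (1.0 - batch["o0"]) * x_tilde
        drift = lambda x, age: dynamics.posterior_drift(
            x, u_ctx, age, params["W_bar"], params["dyn"]["f"],
            params["dyn"]["g"])
        diff = lambda x: dynamics.diffusion(params["dyn"]["sigma"], x)
        state0 = x0
        recon_mu = mu_x
    else:
        include_bg = config.mode != "latent_summary"
        drift = lambda zt, age: dynamics.latent_drift(
            zt, u_ctx, age, params["lat_f"], include_background=include_bg) \
            + _latent_g(params["lat_g"], zt, u_ctx, age, include_bg)
        diff = lambda zt: dynamics.diffusion(params["lat_f"]["sigma"], zt)
        state0 = z
        recon_mu = imputer.decode(params["imp"], z, u_ctx, t0)

    # -- posterior SDE (step 4) --
    ens = dynamics.integrate(drift, diff, state0, t0, config.horizon, dt,
                             dW=noise["dW"])
    paths = ens.paths[0]                      # (T, M, n_state)

    # -- hazard and survival (step 5) --
    lam = mortality.hazard_path(params["haz"], paths, u_ctx, t0,
                                batch["offsets"])
    S = mortality.survival_curve(lam, batch["offsets"])
    Sc = anp.clip(S, S_EPS, 1.0 - S_EPS)

    # -- observation likelihood --
    def masked_ll(y, o, x):
        zres = (y - x) / sigma_y
        return anp.sum(o * (-0.5 * zres ** 2 - anp.log(sigma_y)
                            - 0.5 * LOG2PI), axis=-1)

    obs = masked_ll(batch["y0"], batch["o0"], recon_mu)
    K = batch["y"].shape[1]
    for k in range(1, K):
        sel = batch["valid"][:, k]
        if not np.any(sel):
            continue
        xk = _gather(paths, batch["k_idx"][:, k])
        if config.mode != "network":
            xk = imputer.decode(params["imp"], xk, u_ctx,
                                t0 + batch["k_idx"][:, k] * dt)
        obs = obs + sel * masked_ll(batch["y"][:, k], batch["o"][:, k], xk)

    # -- survival likelihood --
    lam_a = _gather(lam, batch["ia"])
    S_a = _gather(Sc, batch["ia"])
    unc = (1.0 - batch["c"]) * (anp.log(lam_a) + anp.log(S_a))
    cens = batch["c"] * anp.sum(batch["cens_w"] * anp.log(Sc), axis=0)
    dead = (1.0 - batch["c"]) * anp.sum(
        batch["dead_w"] * anp.log(1.0 - Sc), axis=0)
    surv = unc + cens + dead

    # -- path penalty (Girsanov KL of the trajectory posterior) --
    flat = anp.reshape(paths, (T * M, paths.shape[2]))
    ages = (t0[None, :] + batch["offsets"][:, None]).reshape(-1)
    if config.mode == "network":
        b = anp.exp(params["log_b"])
        eps_l = -np.sign(noise["U_w"]) * anp.log1p(-2.0 * np.abs(noise["U_w"]))
        W_s = params["W_bar"] + b * eps_l
        u_flat = np.tile(u_ctx, (T, 1))
        g_in = anp.concatenate(
            [flat, dynamics.scale_age(ages).reshape(-1, 1), u_flat], axis=1)
        from ._nnops import mlp_apply
        g_flat = mlp_apply(params["dyn"]["g"], g_in)
        sig_flat = dynamics.diffusion(params["dyn"]["sigma"], flat)
        dWm = (W_s - params["W_bar"]) * (1.0 - anp.eye(W_s.shape[0]))
        mism = anp.dot(flat, dWm.T) - g_flat
    else:
        include_bg = config.mode != "latent_summary"
        g_flat = _latent_g(params["lat_g"], flat,
                           np.tile(u_ctx, (T, 1)), ages, include_bg)
        sig_flat = dynamics.diffusion(params["lat_f"]["sigma"], flat)
        mism = -g_flat
    integrand = anp.reshape(anp.sum((mism / sig_flat) ** 2, axis=1), (T, M))
    pen = -0.5 * anp.sum(batch["pen_w"] * integrand, axis=0)

    # -- latent KL per individual --
    klz = kl_latent(mu_z, sigma_z, log_det)

    per_ind = obs + surv + beta_xz * (pen - klz)
    s = batch["s"]
    wmean = anp.sum(s * per_ind) / np.sum(s)

    # -- global parameter KLs --
    kl_theta = kl_gamma(anp.exp(params["log_alpha"]),
                        anp.exp(params["log_beta"]), config.prior_gamma)
    if config.mode == "network":
        off = 1.0 - np.eye(params["W_bar"].shape[0])
        kl_theta = kl_theta + kl_laplace(
            params["W_bar"] * off,
            anp.exp(params["log_b"]) * off + np.eye(off.shape[0]) * 0.05,
            config.prior_w_scale)
    return -(wmean - beta_W * kl_theta * kl_scale)


def _latent_g(g_params, zt, u_ctx, age, include_bg):
    from ._nnops import mlp_apply
    a = dynamics.scale_age(np.asarray(age)).reshape(-1, 1) \
        * anp.ones((zt.shape[0], 1))
    if include_bg:
        inp = anp.concatenate([zt, a, u_ctx], axis=1)
    else:
        inp = anp.concatenate([zt, a], axis=1)
    return mlp_apply(g_params, inp)


def elbo(batch, state: VariationalState, betas, rng) -> float:
    """One stochastic evaluation of the training loss on a prepared batch."""
    noise = sample_noise(batch, state.config, rng)
    return float(getval(elbo_loss(state.params, batch, noise, betas,
                                  state.config)))


# ---------------------------------------------------------------------------
# Training loop


class _Adam:
    def __init__(self, x0, lr):
        self.m = np.zeros_like(x0)
        self.v = np.zeros_like(x0)
        self.t = 0
        self.lr = lr

    def step(self, x, g, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * g
        self.v = b2 * self.v + (1 - b2) * g * g
        mhat = self.m / (1 - b1 ** self.t)
        vhat = self.v / (1 - b2 ** self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + eps)


def _corrupt_into(batch, cohort, config, pop_stats, rng):
    """Refresh the encoder inputs with a new corruption draw."""
    sex = cohort.u[:, 0] if cohort.n_background else np.zeros(batch["M"])
    y_tilde, keep = dataio.corrupt_baseline(
        cohort.y0, cohort.o0, config.keep_prob, pop_stats,
        cohort.t0, sex, rng)
    batch["y_enc"] = y_tilde
    batch["o_enc"] = keep * cohort.o0


def train(cohort: CohortDataset, config: TrainConfig = None, rng=None,
          val_cohort: CohortDataset = None, verbose=False,
          callback: Callable = None) -> VariationalState:
    """Fit the model by stochastic variational inference.

    Adam with the configured batch size and learning rate, plateau decay of
    the learning rate on the validation loss, KL annealing per the config
    windows, fresh corruption masking each epoch, and best-validation
    checkpointing.  Fully seed-reproducible.  Divergence (non-finite loss)
    aborts and returns the last finite checkpoint.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    sex = cohort.u[:, 0] if cohort.n_background else np.zeros(cohort.n_individuals)
    pop_stats = PopulationStats.fit(cohort.y0, cohort.o0, cohort.t0, sex)
    state = init_state(cohort.n_vars, cohort.n_background, config, rng,
                       schema=cohort.schema, pop_stats=pop_stats)
    if config.epochs == 0:
        return state
    flat, unflat = flatten(state.params)
    opt = _Adam(flat, config.lr)
    vg = value_and_grad(elbo_loss)

    full = prepare_batch(cohort, config)
    vbatch = prepare_batch(val_cohort, config) if val_cohort is not None else None
    if vbatch is not None:
        vsex = val_cohort.u[:, 0]
        vmean, _ = pop_stats.lookup(val_cohort.t0, vsex)
        vbatch["y_enc"] = val_cohort.o0 * val_cohort.y0 \
            + (1.0 - val_cohort.o0) * vmean
        vbatch["o_enc"] = val_cohort.o0
        val_noise = sample_noise(vbatch, config, rng)

    M = cohort.n_individuals
    # the likelihood part of the loss is a weighted per-individual average,
    # so the once-per-dataset parameter KL must be scaled down accordingly
    kl_scale = 1.0 / float(np.sum(cohort.s))
    best_val = np.inf
    best_flat = flat.copy()
    best_epoch = 0
    last_finite = flat.copy()
    lr_wait = 0
    for epoch in range(config.epochs):
        betas = anneal(epoch, config)
        perm = rng.permutation(M)
        nb = max(1, int(np.ceil(M / config.batch_size)))
        ep_loss = 0.0
        _corrupt_into(full, cohort, config, pop_stats, rng)
        for i in range(nb):
            idx = perm[i * config.batch_size:(i + 1) * config.batch_size]
            if nb == 1:
                batch = full
            else:
                batch = _slice_batch(full, idx)
            noise = sample_noise(batch, config, rng)
            params = unflat(flat)
            loss, grad = vg(params, batch, noise, betas, config, kl_scale)
            if not np.isfinite(loss):
                state.params = unflat(last_finite)
                state.history.append(
                    {"epoch": epoch, "train_loss": float(loss),
                     "event": "diverged"})
                return state
            last_finite = flat.copy()
            gflat, _ = flatten(grad)
            flat = opt.step(flat, gflat)
            ep_loss += float(loss) * len(idx)
        ep_loss /= M
        # validation / schedule
        if vbatch is not None:
            vparams = unflat(flat)
            vloss = float(getval(elbo_loss(vparams, vbatch, val_noise,
                                           betas, config, kl_scale)))
        else:
            vloss = ep_loss
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_flat = flat.copy()
            best_epoch = epoch
            lr_wait = 0
        else:
            lr_wait += 1
            if lr_wait >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                lr_wait = 0
        state.history.append({"epoch": epoch, "train_loss": ep_loss,
                              "val_loss": vloss, "lr": opt.lr,
                              "beta_xz": betas[0], "beta_W": betas[1]})
        if verbose and (epoch % 10 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:4d}  train {ep_loss:10.4f}  "
                  f"val {vloss:10.4f}  lr {opt.lr:.2e}")
        if callback is not None:
            callback(epoch, state, ep_loss, vloss)
    state.params = unflat(best_flat if vbatch is not None else flat)
    state.history.append({"epoch": config.epochs, "event": "done",
                          "best_epoch": best_epoch, "best_val": best_val})
    return state


def _slice_batch(full, idx):
    out = {}
    for key, val in full.items():
        if key in ("offsets", "T"):
            out[key] = val
        elif key in ("cens_w", "dead_w", "pen_w"):
            out[key] = val[:, idx]
        elif isinstance(val, np.ndarray) and val.ndim >= 1 \
                and val.shape[0] == full["M"]:
            out[key] = val[idx]
        else:
            out[key] = val
    out["M"] = len(idx)
    return out
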
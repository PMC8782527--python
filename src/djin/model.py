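"""Model facade: build from a cohort, fit, then predict/generate/inspect.

`DJINModel` wraps a training cohort and configuration; `fit()` runs the
stochastic variational training loop and returns a `DJINResults` carrying
the variational state, training history, posterior network views, and
prediction / simulation / imputation methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dynamics, evaluate, imputer, inference, mortality
from .dataio import CohortDataset, PopulationStats, VariableSchema, read_cohort
from .inference import TrainConfig, VariationalState
from .netanalysis import InteractionPosterior

__all__ = ["DJINModel", "DJINResults"]


class DJINModel:
    """Joint network-SDE model of health trajectories and survival.

    Parameters
    ----------
    cohort : CohortDataset
        Training data (transformed scale, replicated and weighted).
    config : TrainConfig, optional
        Hyperparameters; defaults follow the published schedule.
    val_cohort : CohortDataset, optional
        Validation data for the plateau schedule and checkpoint selection.
    """

    def __init__(self, cohort: CohortDataset, config: TrainConfig = None,
                 val_cohort: CohortDataset = None):
        self.cohort = cohort
        self.config = config or TrainConfig()
        self.val_cohort = val_cohort

    @classmethod
    def from_tables(cls, visits_path, individuals_path,
                    schema: VariableSchema, config: TrainConfig = None,
                    val_paths=None):
        cohort = read_cohort(visits_path, individuals_path, schema)
        val = read_cohort(*val_paths, schema) if val_paths else None
        return cls(cohort, config=config, val_cohort=val)

    def fit(self, seed=None, verbose=False, callback=None) -> "DJINResults":
        """Run stochastic variational inference; returns the results object."""
        cfg = self.config
        if seed is not None:
            from dataclasses import replace
            cfg = replace(cfg, seed=seed)
        state = inference.train(self.cohort, cfg, val_cohort=self.val_cohort,
                                verbose=verbose, callback=callback)
        return DJINResults(self, state)


class DJINResults:
    """Fitted-model results: posteriors, diagnostics and simulation."""

    def __init__(self, model: DJINModel, state: VariationalState):
        self.model = model
        self.state = state

    # -- posterior views -------------------------------------------------
    @property
    def params(self) -> dict:
        return self.state.params

    @property
    def W_bar(self) -> np.ndarray:
        return self.state.W_bar

    @property
    def sigma_y(self) -> np.ndarray:
        return self.state.sigma_y

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.state.history)

    def interaction_posterior(self, level=0.99) -> InteractionPosterior:
        names = self.state.schema.names if self.state.schema else None
        return InteractionPosterior(W_bar=self.state.W_bar, b=self.state.b,
                                    level=level, names=names)

    def summary(self) -> str:
        """Plain-text summary of the fit and the robust network."""
        post = self.interaction_posterior()
        edges = post.edge_table()
        robust = edges[edges.robust].reindex(
            edges[edges.robust]["mean"].abs().sort_values(ascending=False).index)
        hist = self.history
        done = hist[hist.get("event").notna()] if "event" in hist else hist.iloc[0:0]
        lines = [
            "Joint network-SDE aging model",
            "=" * 46,
            f"health variables (N):      {self.state.n_vars}",
            f"background variables (B):  {self.state.n_background}",
            f"individuals (replicas):    {self.model.cohort.n_individuals}",
            f"epochs run:                {int(hist['epoch'].max()) if len(hist) else 0}",
            f"mean sigma_y (posterior):  {self.sigma_y.mean():.4f}",
            f"robust edges (99% CI):     {int(post.pruned_mask.sum())} "
            f"/ {self.state.n_vars * (self.state.n_vars - 1)}",
        ]
        if len(done) and "best_val" in done.columns:
            bv = done["best_val"].dropna()
            if len(bv):
                lines.append(f"best validation loss:      {float(bv.iloc[-1]):.4f}")
        if len(robust):
            lines.append("")
            lines.append("strongest robust edges (source -> target, mean [lo, hi]):")
            for _, r in robust.head(10).iterrows():
                lines.append(f"  {r['source']:>8s} -> {r['target']:<8s} "
                             f"{r['mean']:+.3f}  [{r['lo']:+.3f}, {r['hi']:+.3f}]")
        return "\n".join(lines)

    # -- prediction ------------------------------------------------------
    def _u_ctx(self, cohort):
        return np.concatenate([cohort.u, cohort.u_mask], axis=1)

    def _fill_baseline(self, cohort):
        ps = self.state.pop_stats
        if ps is None:
            mean = np.zeros_like(cohort.y0)
            sd = np.ones_like(cohort.y0)
        else:
            sex = cohort.u[:, 0] if cohort.n_background else np.zeros(cohort.n_individuals)
            mean, sd = ps.lookup(cohort.t0, sex)
        return mean, sd

    def _drift_diff(self, mode="prior"):
        p = self.state.params
        cfg = self.state.config

        def make(u_ctx):
            if cfg.mode == "network":
                if mode == "prior":
                    drift = lambda x, age: dynamics.prior_drift(
                        x, u_ctx, age, p["W_bar"], p["dyn"]["f"])
                else:
                    drift = lambda x, age: dynamics.posterior_drift(
                        x, u_ctx, age, p["W_bar"], p["dyn"]["f"], p["dyn"]["g"])
                diff = lambda x: dynamics.diffusion(p["dyn"]["sigma"], x)
            else:
                include_bg = cfg.mode != "latent_summary"
                drift = lambda z, age: dynamics.latent_drift(
                    z, u_ctx, age, p["lat_f"], include_background=include_bg)
                diff = lambda z: dynamics.diffusion(p["lat_f"]["sigma"], z)
            return drift, diff

        return make

    def predict(self, cohort: CohortDataset, n_samples=10, rng=None,
                horizon=None, mode="prior") -> evaluate.PredictionSet:
        """Predict trajectories and survival from each baseline state.

        Baselines are multiply imputed from the VAE posterior, trajectories
        sampled from the fitted SDE (``mode='prior'`` uses the network
        drift W_bar x + f; ``'posterior'`` adds the correction g), hazards
        run along each sampled path; trajectory means and mean survival
        curves over the samples are returned as a
        :class:`~djin.evaluate.PredictionSet`.
        """
        rng = np.random.default_rng(rng)
        cfg = self.state.config
        p = self.state.params
        horizon = cfg.horizon if horizon is None else horizon
        u_ctx = self._u_ctx(cohort)
        t0 = cohort.t0
        mean, sd = self._fill_baseline(cohort)
        sigma_y = self.sigma_y
        make = self._drift_diff(mode)
        drift, diff = make(u_ctx)
        M, N = cohort.y0.shape
        trajs, survs = [], []
        for _ in range(n_samples):
            y_tilde = cohort.o0 * cohort.y0 + (1 - cohort.o0) * mean
            z, _, _ = imputer.sample_posterior(
                p["imp"], y_tilde, cohort.o0, u_ctx, t0, rng=rng)
            if cfg.mode == "network":
                mu_x = imputer.decode(p["imp"], z, u_ctx, t0)
                x_tilde = mu_x + sigma_y * rng.standard_normal((M, N))
                state0 = cohort.o0 * cohort.y0 + (1 - cohort.o0) * x_tilde
            else:
                state0 = z
            ens = dynamics.integrate(drift, diff, state0, t0, horizon,
                                     cfg.dt, n_paths=1, rng=rng)
            path = ens.paths[0]
            lam = mortality.hazard_path(p["haz"], path, u_ctx, t0, ens.offsets)
            S = mortality.survival_curve(lam, ens.offsets)
            if cfg.mode != "network":
                dec = [imputer.decode(p["imp"], path[j], u_ctx,
                                      t0 + ens.offsets[j])
                       for j in range(path.shape[0])]
                path = np.stack(dec, axis=0)
            trajs.append(np.asarray(path))
            survs.append(np.asarray(S))
        offsets = dynamics.make_grid(horizon, cfg.dt)
        traj = np.mean(trajs, axis=0).transpose(1, 0, 2)   # (M, T, N)
        surv = np.mean(survs, axis=0).T                    # (M, T)
        return evaluate.PredictionSet(
            offsets=offsets, t0=t0, traj=traj, surv=surv,
            times=cohort.times, y=cohort.y, o=cohort.o,
            a=cohort.a, c=cohort.c, s=cohort.s, schema=cohort.schema)

    def impute_baseline(self, cohort: CohortDataset, n_samples=10, rng=None):
        """Multiple imputation of missing baseline variables (see
        :func:`djin.imputer.impute`)."""
        mean, sd = self._fill_baseline(cohort)
        return imputer.impute(
            self.params["imp"], cohort.y0, cohort.o0, self._u_ctx(cohort),
            cohort.t0, self.sigma_y, n_samples, rng,
            pop_mean=mean, pop_sd=sd)

    def generate_population(self, cohort: CohortDataset, rng=None,
                            horizon=None):
        """Generate one synthetic individual per test individual.

        Uses only (u, t0): a baseline is drawn from the latent prior
        through the flows and decoder, the network SDE evolves it, death
        ages are sampled from the recurrent hazard along the path, and
        measurement noise is added.  Returns a dict with the grid,
        synthetic observations and sampled outcomes.
        """
        rng = np.random.default_rng(rng)
        cfg = self.state.config
        p = self.state.params
        horizon = cfg.horizon if horizon is None else horizon
        u_ctx = self._u_ctx(cohort)
        t0 = cohort.t0
        mean, sd = self._fill_baseline(cohort)
        x0 = imputer.generate_baseline(
            p["imp"], u_ctx, t0, self.sigma_y, 1, rng,
            pop_mean=mean, pop_sd=sd)[0]
        make = self._drift_diff("prior")
        drift, diff = make(u_ctx)
        ens = dynamics.integrate(drift, diff, x0, t0, horizon, cfg.dt,
                                 n_paths=1, rng=rng)
        path = ens.paths[0]
        lam = np.asarray(mortality.hazard_path(p["haz"], path, u_ctx, t0,
                                               ens.offsets))
        death = mortality.sample_death(lam, cfg.dt, rng, t0=t0,
                                       offsets=ens.offsets)
        M, N = x0.shape
        y_syn = np.asarray(path).transpose(1, 0, 2) \
            + self.sigma_y * rng.standard_normal((M, len(ens.offsets), N))
        return {"offsets": ens.offsets, "t0": t0, "x": np.asarray(path),
                "y": y_syn, "death_age": death, "u": cohort.u}

    def save(self, path):
        self.state.save(path)
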
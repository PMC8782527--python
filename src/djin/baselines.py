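"""Linear comparison models.

Three baselines frame the joint model's performance: an elastic-net
proportional-hazards model with the Breslow cumulative baseline hazard,

    lambda(t | t0, y0, u) = exp(beta0 t0 + beta_y . y0 + beta_u . u),
    S(t | .) = exp(-Lambda0(t) exp(linear predictor)),

per-variable elastic-net linear trajectory models

    y_i(t) = y0_i + (beta0_i t0 + beta1_i . y0 + beta2_i . u) (t - t0),

and MICE-style chained-equation imputation with random-forest conditional
models.  The time axis of the Cox model is years from baseline; baseline
age enters as a covariate.  Elastic-net penalties default to published
search optima; the regularization is the scikit-learn form
alpha * (l1_ratio ||b||_1 + (1 - l1_ratio)/2 ||b||_2^2).

All three are thin orchestration over scikit-survival and scikit-learn;
they are baseline support, not novel computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import ElasticNet
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "CoxModel",
    "cox_fit",
    "cox_survival",
    "LinearTrajectoryModel",
    "linear_traj_fit",
    "linear_traj_predict",
    "mice_rf_impute",
    "COX_PENALTIES",
    "TRAJ_PENALTIES",
]

# published random-search optima, used as fixed defaults
COX_PENALTIES = {"alpha": 0.00016, "l1_ratio": 0.15613}
TRAJ_PENALTIES = {"alpha": 0.40423, "l1_ratio": 0.55942}
MICE_DEFAULTS = {"n_trees": 40, "max_depth": 10}


@dataclass
class CoxModel:
    """Fitted elastic-net Cox model with its Breslow baseline."""

    estimator: CoxnetSurvivalAnalysis
    alpha: float
    l1_ratio: float

    @property
    def coef(self) -> np.ndarray:
        return self.estimator.coef_[:, 0]

    def breslow(self):
        """Step-function cumulative baseline hazard Lambda0(t).

        Paired with :meth:`linear_predictor` (which includes the fitting
        library's centering offset): S(t|x) = exp(-Lambda0(t) e^{lp(x)}).
        """
        fn = self.estimator._baseline_models[0].cum_baseline_hazard_
        return fn.x, fn.y

    def linear_predictor(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, float))


def cox_fit(X, time, event, alpha=None, l1_ratio=None) -> CoxModel:
    """Elastic-net-penalized partial-likelihood fit.

    ``X`` stacks the covariates (baseline age, baseline health state,
    background); ``time`` is years from baseline; ``event`` True for
    deaths.  Raises when the training data contain no events.
    """
    event = np.asarray(event, bool)
    if not event.any():
        raise ValueError("no events in training data")
    alpha = COX_PENALTIES["alpha"] if alpha is None else alpha
    l1_ratio = COX_PENALTIES["l1_ratio"] if l1_ratio is None else l1_ratio
    est = CoxnetSurvivalAnalysis(alphas=[alpha], l1_ratio=l1_ratio,
                                 fit_baseline_model=True)
    est.fit(np.asarray(X, float), Surv.from_arrays(event, np.asarray(time)))
    return CoxModel(estimator=est, alpha=alpha, l1_ratio=l1_ratio)


def cox_survival(model: CoxModel, X, t):
    """S(t | X) = exp(-Lambda0(t) exp(X beta)); t in years from baseline.

    Times before the first event give S = 1.  Returns (len(X), len(t)).
    """
    X = np.atleast_2d(np.asarray(X, float))
    t = np.atleast_1d(np.asarray(t, float))
    fns = model.estimator.predict_survival_function(X)
    out = np.empty((len(X), len(t)))
    for i, fn in enumerate(fns):
        lo = fn.x[0]
        vals = fn(np.clip(t, lo, fn.x[-1]))
        out[i] = np.where(t < lo, 1.0, vals)
    return out


# ---------------------------------------------------------------------------
# Linear trajectory model


@dataclass
class LinearTrajectoryModel:
    """Per-variable elastic-net slope models; unfit variables flagged."""

    models: list
    fitted: np.ndarray
    alpha: float
    l1_ratio: float


def linear_traj_fit(y0, u, t0, follow_times, follow_y, follow_o,
                    alpha=None, l1_ratio=None) -> LinearTrajectoryModel:
    """Fit the slope model for each health variable.

    For each variable i, every (baseline, follow-up) pair with the variable
    observed at both ends contributes one row: target slope
    (y_i(t_k) - y0_i)/(t_k - t0), features (t0, y0, u).  ``y0`` must be
    complete (impute first, e.g. with :func:`mice_rf_impute`).  A variable
    never observed at two times is flagged unfit and predicts a flat
    trajectory.
    """
    alpha = TRAJ_PENALTIES["alpha"] if alpha is None else alpha
    l1_ratio = TRAJ_PENALTIES["l1_ratio"] if l1_ratio is None else l1_ratio
    y0 = np.asarray(y0, float)
    M, N = y0.shape
    feats = np.column_stack([np.asarray(t0, float), y0, np.asarray(u, float)])
    models = []
    fitted = np.zeros(N, dtype=bool)
    for i in range(N):
        rows_X, rows_t = [], []
        for m in range(M):
            for k in range(follow_times.shape[1]):
                tk = follow_times[m, k]
                if not np.isfinite(tk) or tk <= t0[m] or not follow_o[m, k, i]:
                    continue
                rows_X.append(feats[m])
                rows_t.append((follow_y[m, k, i] - y0[m, i]) / (tk - t0[m]))
        if len(rows_t) >= 2:
            mdl = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000)
            mdl.fit(np.array(rows_X), np.array(rows_t))
            models.append(mdl)
            fitted[i] = True
        else:
            models.append(None)
    return LinearTrajectoryModel(models=models, fitted=fitted, alpha=alpha,
                                 l1_ratio=l1_ratio)


def linear_traj_predict(model: LinearTrajectoryModel, y0, u, t0, t):
    """Predict y(t) for all variables; exactly y0 at t = t0."""
    y0 = np.atleast_2d(np.asarray(y0, float))
    u = np.atleast_2d(np.asarray(u, float))
    t0 = np.atleast_1d(np.asarray(t0, float))
    t = np.asarray(t, float)
    feats = np.column_stack([t0, y0, u])
    N = y0.shape[1]
    slopes = np.zeros((len(y0), N))
    for i, mdl in enumerate(model.models):
        if mdl is not None:
            slopes[:, i] = mdl.predict(feats)
    dtv = (t - t0)[:, None] if np.ndim(t) else (t - t0)[:, None]
    return y0 + slopes * dtv


# ---------------------------------------------------------------------------
# MICE with random forests


def mice_rf_impute(table, n_trees=None, max_depth=None, rng=None,
                   max_iter=5):
    """Chained-equation imputation with random-forest conditional models.

    Returns the mean-of-estimates completion of ``table`` (2-D array or
    DataFrame with NaN missing).  A fully missing column is an error.
    Deterministic given ``rng``.
    """
    import pandas as pd

    n_trees = MICE_DEFAULTS["n_trees"] if n_trees is None else n_trees
    max_depth = MICE_DEFAULTS["max_depth"] if max_depth is None else max_depth
    was_df = isinstance(table, pd.DataFrame)
    arr = np.asarray(table, float) if not was_df else table.to_numpy(float)
    if np.any(np.all(~np.isfinite(arr), axis=0)):
        raise ValueError("column fully missing; cannot impute")
    seed = int(np.random.default_rng(rng).integers(0, 2 ** 31 - 1))
    imp = IterativeImputer(
        estimator=RandomForestRegressor(
            n_estimators=n_trees, max_depth=max_depth, random_state=seed),
        max_iter=max_iter, random_state=seed, sample_posterior=False)
    done = imp.fit_transform(arr)
    if was_df:
        return pd.DataFrame(done, index=table.index, columns=table.columns)
    return done
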
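"""Evaluation metrics for trajectory and survival predictions.

Implements weighted raw-scale RMSE (absolute and relative to an age/sex
matched population-mean predictor), the time-dependent concordance index
for crossing survival curves, the IPCW Brier score and its integral over
the observed death-age range, the D-calibration chi-square test of survival
probabilities, and the two-sample logistic-regression test of synthetic
population realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .dataio import VariableSchema, invert_transform

__all__ = [
    "PredictionSet",
    "rmse",
    "AgeSexMeans",
    "c_index_td",
    "censoring_km",
    "brier",
    "integrated_brier",
    "d_calibration",
    "sample_outcomes_from_curves",
    "population_discriminator",
]


@dataclass
class PredictionSet:
    """Aligned predictions and follow-up observations for a test cohort.

    ``offsets`` are years from baseline; ``traj`` is (M, T, N) predicted
    trajectory means on the transformed scale, ``surv`` (M, T) predicted
    survival.  ``times``/``y``/``o`` are the padded follow-up visit arrays
    from the cohort, ``a``/``c``/``s``/``t0`` the outcomes, baseline ages
    and weights.
    """

    offsets: np.ndarray
    t0: np.ndarray
    traj: np.ndarray
    surv: np.ndarray
    times: np.ndarray
    y: np.ndarray
    o: np.ndarray
    a: np.ndarray
    c: np.ndarray
    s: np.ndarray
    schema: VariableSchema | None = None

    @property
    def ages(self) -> np.ndarray:
        return self.t0[:, None] + self.offsets[None, :]

    def surv_at(self, m, t):
        """Interpolated survival of individual m at age(s) t."""
        return np.interp(t, self.ages[m], self.surv[m])


# ---------------------------------------------------------------------------
# RMSE


def rmse(pred, obs, mask, weights, schema: VariableSchema = None,
         variable: int = None):
    """Weighted root-mean-square error on the raw scale.

    ``pred``/``obs`` are transformed-scale arrays; when ``schema`` is given
    both are inverse-transformed first (per-variable when ``variable``
    selects a column).  Returns NaN when nothing is observed.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    mask = np.asarray(mask, float)
    w = np.asarray(weights, float)
    if schema is not None:
        if variable is not None:
            sub = VariableSchema(
                names=[schema.names[variable]],
                log_flags=schema.log_flags[[variable]],
                train_mean=schema.train_mean[[variable]],
                train_sd=schema.train_sd[[variable]])
            pred = invert_transform(pred[..., None], sub)[..., 0]
            obs = invert_transform(obs[..., None], sub)[..., 0]
        else:
            pred = invert_transform(pred, schema)
            obs = invert_transform(obs, schema)
    w = np.broadcast_to(w.reshape(w.shape + (1,) * (pred.ndim - w.ndim)),
                        pred.shape)
    wm = w * mask
    tot = wm.sum()
    if tot == 0:
        return np.nan
    return float(np.sqrt(np.sum(wm * np.nan_to_num(pred - obs) ** 2) / tot))


class AgeSexMeans:
    """Age/sex-matched sample-mean predictor, the RMSE normalizer.

    Means are computed per variable from all observed visit values in the
    reference (training) cohort, stratified by sex and 5-year age bin at
    the visit.  Relative RMSE divides a model's RMSE by this predictor's
    RMSE, so the predictor itself scores exactly 1.
    """

    def __init__(self, cohort, bin_width=5.0):
        ages, sexes, ys, os_ = [], [], [], []
        for m in range(cohort.n_individuals):
            k = int(cohort.visit_mask[m].sum())
            ages.append(cohort.times[m, :k])
            sexes.append(np.full(k, cohort.u[m, 0]))
            ys.append(cohort.y[m, :k])
            os_.append(cohort.o[m, :k])
        ages = np.concatenate(ages)
        sexes = (np.concatenate(sexes) > 0.5).astype(int)
        ys = np.concatenate(ys)
        os_ = np.concatenate(os_)
        self.bin_width = bin_width
        self.lo = np.floor(ages.min() / bin_width) * bin_width
        nb = int(np.ceil((ages.max() - self.lo) / bin_width)) + 1
        N = ys.shape[1]
        self.mean = np.zeros((2, nb, N))
        glob = np.array([ys[os_[:, j] > 0, j].mean() if (os_[:, j] > 0).any()
                         else 0.0 for j in range(N)])
        bins = np.clip(((ages - self.lo) / bin_width).astype(int), 0, nb - 1)
        for sx in (0, 1):
            for b in range(nb):
                sel = (sexes == sx) & (bins == b)
                for j in range(N):
                    m = sel & (os_[:, j] > 0)
                    self.mean[sx, b, j] = ys[m, j].mean() if m.any() else glob[j]

    def predict(self, age, sex):
        age = np.atleast_1d(np.asarray(age, float))
        sex = (np.atleast_1d(np.asarray(sex, float)) > 0.5).astype(int)
        bins = np.clip(((age - self.lo) / self.bin_width).astype(int), 0,
                       self.mean.shape[1] - 1)
        return self.mean[sex, bins]


# ---------------------------------------------------------------------------
# Survival metrics


def c_index_td(pred: PredictionSet, *, source_id=None, t0_range=None):
    """Time-dependent concordance index.

    Over comparable pairs (m1 uncensored, a1 < a2), the weighted fraction
    where the model assigns the earlier-dying individual the lower survival
    at the earlier death age: S^(m1)(a1) < S^(m2)(a1).  Ties in death age
    are excluded by the strict inequality; ties in S count 0.  Pairs of
    replicas from the same source individual are excluded when
    ``source_id`` is given.  Returns NaN when no pair is comparable.
    """
    a, c, s = pred.a, pred.c.astype(int), pred.s
    M = len(a)
    keep = np.ones(M, dtype=bool)
    if t0_range is not None:
        keep = (pred.t0 >= t0_range[0]) & (pred.t0 < t0_range[1])
    # S_self[m] = S^(m)(a^(m)) ; Smat[m2, m1] = S^(m2)(a^(m1))
    S_self = np.array([pred.surv_at(m, a[m]) for m in range(M)])
    num = den = 0.0
    for m1 in range(M):
        if c[m1] or not keep[m1]:
            continue
        comp = (a > a[m1]) & keep
        if source_id is not None:
            comp &= source_id != source_id[m1]
        if not comp.any():
            continue
        idx = np.where(comp)[0]
        S2 = np.array([pred.surv_at(m2, a[m1]) for m2 in idx])
        w = s[m1] * s[idx]
        den += w.sum()
        num += w[S_self[m1] < S2].sum()
    if den == 0:
        return np.nan
    return float(num / den)


def censoring_km(a, c):
    """Kaplan-Meier estimate G(t) of the censoring survival distribution.

    Censorings are the events and deaths are the censorings.  Returns a
    right-continuous step-function callable.
    """
    a = np.asarray(a, float)
    c = np.asarray(c, int)
    if len(a) == 0:
        raise ValueError("empty outcome list")
    km = KaplanMeierFitter()
    km.fit(a, event_observed=c)
    times = km.survival_function_.index.to_numpy(float)
    vals = km.survival_function_.iloc[:, 0].to_numpy(float)

    def G(t):
        t = np.asarray(t, float)
        idx = np.searchsorted(times, t, side="right") - 1
        out = np.where(idx >= 0, vals[np.clip(idx, 0, len(vals) - 1)], 1.0)
        return out if out.ndim else float(out)

    return G


def brier(pred: PredictionSet, t, G=None):
    """IPCW Brier score of the survival predictions at age ``t``.

    Dead-by-t individuals contribute S(t)^2 / G(a); alive-at-t individuals
    (1 - S(t))^2 / G(t).  Individuals whose required G weight is zero are
    excluded (logged via the returned effective weight).  Weighted mean
    over individuals.
    """
    if G is None:
        G = censoring_km(pred.a, pred.c)
    a, c, s = pred.a, pred.c.astype(int), pred.s
    M = len(a)
    S_t = np.array([pred.surv_at(m, t) for m in range(M)])
    dead = (a <= t) & (c == 0)
    alive = a > t
    Ga = np.asarray(G(a), float)
    Gt = float(G(t))
    num = 0.0
    den = 0.0
    for m in range(M):
        if dead[m]:
            if Ga[m] <= 0:
                continue
            num += s[m] * S_t[m] ** 2 / Ga[m]
            den += s[m]
        elif alive[m]:
            if Gt <= 0:
                continue
            num += s[m] * (1.0 - S_t[m]) ** 2 / Gt
            den += s[m]
        else:
            den += s[m]          # censored before t: weight stays in the mean
    if den == 0:
        return np.nan
    return float(num / den)


def integrated_brier(pred: PredictionSet, G=None):
    """Integrate BS(t) over the observed death-age range (trapezoid),
    normalized by the range; evaluation grid = the observed death ages."""
    death_ages = np.unique(pred.a[pred.c == 0])
    if len(death_ages) < 2:
        return np.nan
    if G is None:
        G = censoring_km(pred.a, pred.c)
    bs = np.array([brier(pred, t, G) for t in death_ages])
    ok = np.isfinite(bs)
    t = death_ages[ok]
    return float(np.trapezoid(bs[ok], t) / (t[-1] - t[0]))


def d_calibration(S_at_event, c, n_bins=10):
    """D-calibration: are predicted survival quantiles at event times
    uniform?

    Uncensored individuals fall in the decile of S(a); each censored
    individual's unit mass is spread uniformly over the quantiles below its
    S(a) (it is known only to die somewhere past a).  Pearson chi-square
    against the uniform distribution with n_bins - 1 degrees of freedom.
    """
    S_at_event = np.asarray(S_at_event, float)
    c = np.asarray(c, int)
    n = len(S_at_event)
    if n < n_bins:
        raise ValueError("fewer individuals than bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins)
    for p, cens in zip(S_at_event, c):
        if not cens:
            b = min(int(p * n_bins), n_bins - 1)
            counts[b] += 1.0
        else:
            if p <= 0:
                counts[0] += 1.0
                continue
            overlap = np.clip(np.minimum(edges[1:], p) - edges[:-1], 0.0, None)
            counts += overlap / p
    expected = n / n_bins
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, n_bins - 1))
    return counts, chi2, pval


def sample_outcomes_from_curves(ages, S, rng, censor_age=None):
    """Draw death ages from per-individual survival curves.

    Inverse-CDF sampling on the discrete grid: the death age is the first
    grid age where S drops below a uniform draw (linear interpolation
    within the step).  Individuals whose curve never reaches the draw are
    censored at the end of their grid; ``censor_age`` optionally censors
    earlier.  Returns (a, c).
    """
    rng = np.random.default_rng(rng)
    ages = np.asarray(ages, float)
    S = np.asarray(S, float)
    M = S.shape[0]
    a = np.empty(M)
    c = np.zeros(M, dtype=int)
    u = rng.random(M)
    for m in range(M):
        grid = ages[m] if ages.ndim == 2 else ages
        below = np.where(S[m] < u[m])[0]
        if below.size == 0:
            a[m] = grid[-1]
            c[m] = 1
        else:
            j = below[0]
            if j == 0:
                a[m] = grid[0]
            else:
                s0, s1 = S[m, j - 1], S[m, j]
                frac = (s0 - u[m]) / max(s0 - s1, 1e-12)
                a[m] = grid[j - 1] + frac * (grid[j] - grid[j - 1])
            c[m] = 0
        if censor_age is not None:
            ca = censor_age[m] if np.ndim(censor_age) else censor_age
            if a[m] >= ca:
                a[m] = ca
                c[m] = 1
    return a, c


def matched_missingness_features(cohort, syn, means: "AgeSexMeans"):
    """Observation-level feature rows for the two-sample population test.

    For every real visit the features are (age, health values, background),
    with missing health values filled by the age/sex-matched sample mean.
    The synthetic population contributes one row per matching visit — the
    generated trajectory read at the same visit offset, with the *real*
    individual's missingness pattern applied and the same mean fill — and
    no rows after the synthetic individual's sampled death.  Returns
    (real_X, synth_X, real_strata, synth_strata) with strata = whole years
    from baseline.
    """
    offsets = syn["offsets"]
    real_rows, syn_rows, real_g, syn_g = [], [], [], []
    for m in range(cohort.n_individuals):
        k = int(cohort.visit_mask[m].sum())
        sex = cohort.u[m, 0]
        for j in range(k):
            age = cohort.times[m, j]
            off = age - cohort.t0[m]
            gi = int(off // 2.0) * 2
            fill = means.predict(age, sex)[0]
            o = cohort.o[m, j]
            yr = np.where(o > 0, cohort.y[m, j], fill)
            real_rows.append(np.concatenate([[age], yr, cohort.u[m]]))
            real_g.append(gi)
            jj = int(np.clip(round(off / (offsets[1] - offsets[0])), 0,
                             len(offsets) - 1))
            death = syn["death_age"][m]
            if np.isfinite(death) and cohort.t0[m] + offsets[jj] >= death:
                continue
            ys = np.where(o > 0, syn["y"][m, jj], fill)
            syn_rows.append(np.concatenate([[age], ys, cohort.u[m]]))
            syn_g.append(gi)
    return (np.array(real_rows), np.array(syn_rows),
            np.array(real_g), np.array(syn_g))


# ---------------------------------------------------------------------------
# 2-sample classification test


def population_discriminator(real_X, synth_X, rng, *, strata=None,
                             test_size=0.3, max_imbalance=0.95):
    """Logistic-regression two-sample test of population realism.

    ``real_X``/``synth_X`` are observation-level feature matrices (age,
    health values with the real missingness pattern applied to both and
    mean-filled, background covariates).  Returns held-out accuracy
    (overall, plus per-stratum when ``strata`` — e.g. years-from-baseline
    bins per row — are given as a pair of label arrays).
    """
    rng = np.random.default_rng(rng)
    real_X = np.asarray(real_X, float)
    synth_X = np.asarray(synth_X, float)
    n_r, n_s = len(real_X), len(synth_X)
    frac = n_r / (n_r + n_s)
    if frac > max_imbalance or frac < 1 - max_imbalance:
        raise ValueError("class imbalance exceeds 95/5")
    X = np.vstack([real_X, synth_X])
    y = np.concatenate([np.zeros(n_r), np.ones(n_s)])
    lab = None
    if strata is not None:
        lab = np.concatenate([np.asarray(strata[0]), np.asarray(strata[1])])
    seed = int(rng.integers(0, 2 ** 31 - 1))
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                              stratify=y)
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X[tr], y[tr])
    acc = float(clf.score(X[te], y[te]))
    if lab is None:
        return acc
    per = {}
    for g in np.unique(lab[te]):
        sel = te[lab[te] == g]
        per[float(g)] = float(clf.score(X[sel], y[sel]))
    return acc, per
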
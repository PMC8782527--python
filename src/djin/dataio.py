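"""Cohort schema, transforms, preprocessing and augmentation.

The cohort is tabular longitudinal data: per individual, a baseline age,
strictly increasing visit ages, an N-column health matrix with an
observation mask (1 = observed), B background covariates with their own
missing mask, a death age or last-known-alive age and a censoring flag.
Health values are stored on a transformed scale: skewed variables are
log-transformed and every variable is z-scored with constants estimated on
the training split only.

File dialect: UTF-8 delimited text with a header; one long-format visits
table plus one individuals table keyed by individual id; missing = empty
field; raw (untransformed) units on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSchema",
    "CohortDataset",
    "PopulationStats",
    "fit_schema",
    "apply_transform",
    "invert_transform",
    "deprivatize_ages",
    "carry_forward",
    "finalize_outcomes",
    "replicate_baselines",
    "corrupt_baseline",
    "split_cohort",
    "read_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# Schema


@dataclass
class VariableSchema:
    """Per-variable transform metadata for the health matrix.

    ``log_flags[i]`` marks variables whose raw distribution spans orders of
    magnitude; they are log-transformed before z-scoring.  ``train_mean`` and
    ``train_sd`` are on the transformed (post-log) scale and must come from
    the training split only.  ``upper_bounds`` are optional per-variable raw
    plausibility caps (e.g. gait speed above 4 m/s is a data error); values
    above the cap are set to missing rather than clipped.
    """

    names: list[str]
    log_flags: np.ndarray
    train_mean: np.ndarray
    train_sd: np.ndarray
    background_names: list[str] = field(default_factory=list)
    ordinal_flags: np.ndarray | None = None
    upper_bounds: np.ndarray | None = None

    def __post_init__(self):
        self.log_flags = np.asarray(self.log_flags, dtype=bool)
        self.train_mean = np.asarray(self.train_mean, dtype=float)
        self.train_sd = np.asarray(self.train_sd, dtype=float)
        if self.ordinal_flags is None:
            self.ordinal_flags = np.zeros(len(self.names), dtype=bool)
        else:
            self.ordinal_flags = np.asarray(self.ordinal_flags, dtype=bool)
        if self.upper_bounds is not None:
            self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if np.any(self.train_sd <= 0):
            bad = self.names[int(np.argmax(self.train_sd <= 0))]
            raise ValueError(f"train_sd must be positive (variable {bad!r})")

    @property
    def n_vars(self) -> int:
        return len(self.names)

    @property
    def n_background(self) -> int:
        return len(self.background_names)

    def to_yaml(self, path) -> None:
        doc = {
            "names": list(self.names),
            "log_flags": self.log_flags.astype(int).tolist(),
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "background_names": list(self.background_names),
            "ordinal_flags": self.ordinal_flags.astype(int).tolist(),
            "upper_bounds": None if self.upper_bounds is None
            else [None if not np.isfinite(b) else float(b) for b in self.upper_bounds],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "VariableSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        ub = doc.get("upper_bounds")
        if ub is not None:
            ub = np.array([np.inf if b is None else b for b in ub])
        return cls(
            names=doc["names"],
            log_flags=np.array(doc["log_flags"], dtype=bool),
            train_mean=np.array(doc["train_mean"]),
            train_sd=np.array(doc["train_sd"]),
            background_names=doc.get("background_names", []),
            ordinal_flags=np.array(doc.get("ordinal_flags"), dtype=bool)
            if doc.get("ordinal_flags") is not None else None,
            upper_bounds=ub,
        )

    @staticmethod
    def identity(n_vars: int, background_names=(), names=None) -> "VariableSchema":
        """Schema that leaves values unchanged (mean 0, sd 1, no logs)."""
        names = list(names) if names is not None else [f"x{i}" for i in range(n_vars)]
        return VariableSchema(
            names=names,
            log_flags=np.zeros(n_vars, dtype=bool),
            train_mean=np.zeros(n_vars),
            train_sd=np.ones(n_vars),
            background_names=list(background_names),
        )


def fit_schema(
    raw_table: pd.DataFrame,
    log_rule: Sequence[bool],
    *,
    background_names: Sequence[str] = (),
    ordinal_flags: Sequence[bool] | None = None,
    upper_bounds: Sequence[float] | None = None,
) -> VariableSchema:
    """Estimate z-scoring constants on the (training-split) raw table.

    ``raw_table`` holds one row per observation with one column per health
    variable; NaN marks missing.  ``log_rule`` is an explicit per-variable
    flag list — skewness is not auto-detected.
    """
    names = list(raw_table.columns)
    log_flags = np.asarray(log_rule, dtype=bool)
    if len(log_flags) != len(names):
        raise ValueError("log_rule length must match number of variables")
    means = np.empty(len(names))
    sds = np.empty(len(names))
    for j, name in enumerate(names):
        col = raw_table[name].to_numpy(dtype=float)
        obs = col[np.isfinite(col)]
        if upper_bounds is not None and np.isfinite(upper_bounds[j]):
            obs = obs[obs <= upper_bounds[j]]
        if obs.size == 0 or np.all(obs == obs[0]):
            raise ValueError(f"zero observed variance for variable {name!r}")
        if log_flags[j]:
            if np.any(obs <= 0):
                raise ValueError(
                    f"non-positive value in log-flagged variable {name!r}"
                )
            obs = np.log(obs)
        means[j] = obs.mean()
        sds[j] = obs.std(ddof=0)
        if sds[j] == 0:
            raise ValueError(f"zero observed variance for variable {name!r}")
    return VariableSchema(
        names=names,
        log_flags=log_flags,
        train_mean=means,
        train_sd=sds,
        background_names=list(background_names),
        ordinal_flags=None if ordinal_flags is None
        else np.asarray(ordinal_flags, dtype=bool),
        upper_bounds=None if upper_bounds is None
        else np.asarray(upper_bounds, dtype=float),
    )


def apply_transform(values, mask, schema: VariableSchema):
    """Raw units -> transformed scale; plausibility violations become missing.

    Returns ``(z, mask)``.  Missing entries are left untouched (their content
    is meaningless behind the mask).  Never raises on bad values: a raw value
    above its upper bound, or non-positive under a log flag, is flipped to
    missing and logged.
    """
    values = np.array(values, dtype=float)
    mask = np.array(mask, dtype=float)
    obs = mask > 0
    if schema.upper_bounds is not None:
        bad = obs & (values > schema.upper_bounds)
        if bad.any():
            logger.warning("masking %d implausible values above bounds", bad.sum())
            mask = np.where(bad, 0.0, mask)
            obs = mask > 0
    logged = np.broadcast_to(schema.log_flags, values.shape)
    badlog = obs & logged & (values <= 0)
    if badlog.any():
        logger.warning("masking %d non-positive values under log flags", badlog.sum())
        mask = np.where(badlog, 0.0, mask)
        obs = mask > 0
    safe = np.where(obs & logged, np.maximum(values, 1e-300), values)
    t = np.where(logged, np.log(np.abs(safe) + (safe == 0)), safe)
    z = (t - schema.train_mean) / schema.train_sd
    z = np.where(obs, z, values)
    return z, mask


def invert_transform(z_values, schema: VariableSchema):
    """Transformed scale -> raw units (un-z-score, then exp for log columns)."""
    z = np.asarray(z_values, dtype=float)
    t = z * schema.train_sd + schema.train_mean
    return np.where(schema.log_flags, np.exp(t), t)


# ---------------------------------------------------------------------------
# Age / outcome preprocessing


def deprivatize_ages(age_sequence, privatized, wave_gap: float = 2.0):
    """Fill privatized ages assuming a fixed gap between study waves.

    ``privatized`` is a boolean flag array; each flagged entry becomes the
    previous (possibly filled) entry plus ``wave_gap``.  A flagged entry with
    no preceding known age is an error.  The same rule deprivatizes death
    ages known only by wave.
    """
    ages = np.array(age_sequence, dtype=float)
    priv = np.asarray(privatized, dtype=bool)
    if priv.size and priv[0]:
        raise ValueError("privatized age with no preceding known age")
    for k in range(1, len(ages)):
        if priv[k]:
            ages[k] = ages[k - 1] + wave_gap
    return ages


def carry_forward(values):
    """Last observation carried forward; leading gap back-filled.

    Used for slowly-varying anthropometrics (height-like variables) that are
    measured only at some visits.  NaN marks missing.
    """
    vals = np.array(values, dtype=float)
    last = np.nan
    for k in range(len(vals)):
        if np.isfinite(vals[k]):
            last = vals[k]
        elif np.isfinite(last):
            vals[k] = last
    # back-fill the leading run from the first observed value
    finite = np.isfinite(vals)
    if finite.any():
        first = vals[np.argmax(finite)]
        vals[: int(np.argmax(finite))] = first
    return vals


def finalize_outcomes(visit_ages, death_age=None):
    """Survival outcome convention: ``(a, c)``.

    No recorded death -> censored (c=1) at the last observed age; a recorded
    death -> uncensored (c=0) at the death age.
    """
    visit_ages = np.asarray(visit_ages, dtype=float)
    if death_age is None or (isinstance(death_age, float) and np.isnan(death_age)):
        return float(visit_ages[-1]), 1
    if death_age < visit_ages[0]:
        raise ValueError("death age precedes baseline age")
    return float(death_age), 0


# ---------------------------------------------------------------------------
# Individuals and the padded cohort container


@dataclass
class CohortDataset:
    """Padded cohort arrays, one row per (replica) individual.

    ``times`` is (M, K+1) visit ages padded with NaN; ``visit_mask`` marks
    real visits.  ``y``/``o`` are (M, K+1, N) on the transformed scale with
    o=1 meaning observed.  ``u`` is (M, B) with ``u_mask`` its observed mask
    (missing background entries are zero-filled behind the mask).  ``a`` is
    the event age, ``c`` the censoring flag (1 = censored), ``s`` the
    replication sample weight in (0, 1].
    """

    times: np.ndarray
    visit_mask: np.ndarray
    y: np.ndarray
    o: np.ndarray
    u: np.ndarray
    u_mask: np.ndarray
    a: np.ndarray
    c: np.ndarray
    s: np.ndarray
    source_id: np.ndarray
    schema: VariableSchema | None = None
    prediction_mask: np.ndarray | None = None

    def __post_init__(self):
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self):
        M = self.times.shape[0]
        for name in ("visit_mask", "y", "o", "a", "c", "s", "u", "u_mask",
                     "source_id"):
            if getattr(self, name).shape[0] != M:
                raise ValueError(f"field {name} has wrong leading dimension")
        if not np.all(np.isin(self.o[self.visit_mask.astype(bool)], (0.0, 1.0))):
            raise ValueError("observation mask entries must be 0 or 1")
        if np.any(self.a < self.t0 - 1e-9):
            raise ValueError("event age before baseline age")
        if np.any((self.s <= 0) | (self.s > 1)):
            raise ValueError("sample weights must lie in (0, 1]")
        # visit ages strictly increasing where present
        dt = np.diff(self.times, axis=1)
        both = self.visit_mask[:, 1:].astype(bool) & self.visit_mask[:, :-1].astype(bool)
        if np.any(dt[both] <= 0):
            raise ValueError("visit ages must be strictly increasing")

    # -- views ----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.times.shape[0]

    @property
    def n_vars(self) -> int:
        return self.y.shape[2]

    @property
    def n_background(self) -> int:
        return self.u.shape[1]

    @property
    def t0(self) -> np.ndarray:
        return self.times[:, 0]

    @property
    def y0(self) -> np.ndarray:
        return self.y[:, 0, :]

    @property
    def o0(self) -> np.ndarray:
        return self.o[:, 0, :]

    def subset(self, idx) -> "CohortDataset":
        idx = np.asarray(idx)
        return CohortDataset(
            times=self.times[idx], visit_mask=self.visit_mask[idx],
            y=self.y[idx], o=self.o[idx], u=self.u[idx],
            u_mask=self.u_mask[idx], a=self.a[idx], c=self.c[idx],
            s=self.s[idx], source_id=self.source_id[idx], schema=self.schema,
            prediction_mask=None if self.prediction_mask is None
            else self.prediction_mask[idx],
        )

    @classmethod
    def from_individuals(cls, individuals, schema=None) -> "CohortDataset":
        """Stack a list of per-individual dicts into padded arrays.

        Each dict needs: visit_ages (K+1,), y (K+1, N), o (K+1, N), u (B,),
        u_mask (B,), a, c, s, source_id.
        """
        kmax = max(len(ind["visit_ages"]) for ind in individuals)
        M = len(individuals)
        N = individuals[0]["y"].shape[1]
        B = len(individuals[0]["u"])
        times = np.full((M, kmax), np.nan)
        vmask = np.zeros((M, kmax))
        y = np.zeros((M, kmax, N))
        o = np.zeros((M, kmax, N))
        u = np.zeros((M, B))
        umask = np.zeros((M, B))
        a = np.zeros(M)
        c = np.zeros(M, dtype=int)
        s = np.zeros(M)
        src = np.zeros(M, dtype=int)
        for m, ind in enumerate(individuals):
            k = len(ind["visit_ages"])
            times[m, :k] = ind["visit_ages"]
            vmask[m, :k] = 1.0
            y[m, :k] = ind["y"]
            o[m, :k] = ind["o"]
            u[m] = ind["u"]
            umask[m] = ind["u_mask"]
            a[m] = ind["a"]
            c[m] = ind["c"]
            s[m] = ind.get("s", 1.0)
            src[m] = ind.get("source_id", m)
        return cls(times=times, visit_mask=vmask, y=y, o=o, u=u, u_mask=umask,
                   a=a, c=c, s=s, source_id=src, schema=schema)


# ---------------------------------------------------------------------------
# Augmentation


def replicate_baselines(individual: dict, *, require_followup: bool = False):
    """Expand one individual into one replica per possible baseline wave.

    Every visit wave k becomes the baseline of replica k (its later visits
    retained), so variables measured only at particular waves can appear at
    baseline.  Replicas of one source individual are down-weighted by
    s = 1/(number of replicas) so the source contributes unit total weight.
    With ``require_followup`` (test prediction sets) a replica must keep at
    least one follow-up visit, except that a single-visit individual yields
    its single trivial replica.
    """
    ages = np.asarray(individual["visit_ages"], dtype=float)
    K1 = len(ages)
    starts = list(range(K1))
    if require_followup and K1 > 1:
        starts = [k for k in starts if K1 - k >= 2]
    w = 1.0 / len(starts)
    replicas = []
    for k in starts:
        rep = dict(individual)
        rep["visit_ages"] = ages[k:]
        rep["y"] = np.asarray(individual["y"])[k:]
        rep["o"] = np.asarray(individual["o"])[k:]
        rep["s"] = w
        replicas.append(rep)
    return replicas


def replicate_dataset(dataset: CohortDataset, *,
                      require_followup: bool = False) -> CohortDataset:
    """Apply :func:`replicate_baselines` to every row of a cohort."""
    individuals = []
    for m in range(dataset.n_individuals):
        k = int(dataset.visit_mask[m].sum())
        ind = {
            "visit_ages": dataset.times[m, :k],
            "y": dataset.y[m, :k],
            "o": dataset.o[m, :k],
            "u": dataset.u[m],
            "u_mask": dataset.u_mask[m],
            "a": dataset.a[m],
            "c": int(dataset.c[m]),
            "source_id": int(dataset.source_id[m]),
        }
        individuals.extend(
            replicate_baselines(ind, require_followup=require_followup))
    return CohortDataset.from_individuals(individuals, schema=dataset.schema)


@dataclass
class PopulationStats:
    """Sex- and age-stratified transformed-scale moments for baseline filling.

    Strata are sex (a designated binary background column) crossed with
    5-year baseline-age bins; a global fallback covers empty strata.
    """

    age_edges: np.ndarray
    mean: np.ndarray      # (2, n_bins, N)
    sd: np.ndarray        # (2, n_bins, N)
    count: np.ndarray     # (2, n_bins, N)
    global_mean: np.ndarray
    global_sd: np.ndarray
    sex_column: int = 0

    @classmethod
    def fit(cls, y0, o0, t0, sex, *, bin_width=5.0, sex_column=0):
        y0 = np.asarray(y0, float)
        o0 = np.asarray(o0, float) > 0
        t0 = np.asarray(t0, float)
        sex = (np.asarray(sex, float) > 0.5).astype(int)
        lo = np.floor(t0.min() / bin_width) * bin_width
        hi = np.ceil((t0.max() + 1e-9) / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        n_bins = max(len(edges) - 1, 1)
        N = y0.shape[1]
        mean = np.zeros((2, n_bins, N))
        sd = np.ones((2, n_bins, N))
        count = np.zeros((2, n_bins, N))
        bins = np.clip(np.digitize(t0, edges) - 1, 0, n_bins - 1)
        gmean = np.array([y0[o0[:, j], j].mean() if o0[:, j].any() else 0.0
                          for j in range(N)])
        gsd = np.array([y0[o0[:, j], j].std() if o0[:, j].sum() > 1 else 1.0
                        for j in range(N)])
        gsd = np.where(gsd > 0, gsd, 1.0)
        for sx in (0, 1):
            for b in range(n_bins):
                sel = (sex == sx) & (bins == b)
                for j in range(N):
                    obs = y0[sel & o0[:, j], j]
                    count[sx, b, j] = obs.size
                    if obs.size >= 2:
                        mean[sx, b, j] = obs.mean()
                        sd[sx, b, j] = max(obs.std(), 1e-6)
                    elif obs.size == 1:
                        mean[sx, b, j] = obs[0]
                        sd[sx, b, j] = gsd[j]
                    else:
                        mean[sx, b, j] = gmean[j]
                        sd[sx, b, j] = gsd[j]
        return cls(age_edges=edges, mean=mean, sd=sd, count=count,
                   global_mean=gmean, global_sd=gsd, sex_column=sex_column)

    def lookup(self, t0, sex):
        """Per-individual stratum mean/sd arrays of shape (M, N)."""
        t0 = np.atleast_1d(np.asarray(t0, float))
        sex = (np.atleast_1d(np.asarray(sex, float)) > 0.5).astype(int)
        bins = np.clip(np.digitize(t0, self.age_edges) - 1, 0,
                       self.mean.shape[1] - 1)
        empty = self.count[sex, bins] == 0
        if empty.any():
            logger.warning("population stratum empty for %d entries; "
                           "falling back to global stats", int(empty.sum()))
        mean = np.where(empty, self.global_mean, self.mean[sex, bins])
        sd = np.where(empty, self.global_sd, self.sd[sex, bins])
        return mean, sd


def corrupt_baseline(y0, o0, keep_prob, population_stats, t0, sex, rng):
    """Self-supervision corruption of the baseline health state.

    Each observed entry is kept with probability ``keep_prob``; dropped and
    genuinely missing entries are temporarily filled with a Gaussian draw
    from the matching sex/age stratum.  Returns ``(y_tilde, keep)`` where
    ``keep`` is the Bernoulli keep indicator (the corruption indicator for
    reconstruction is ``o0 * (1 - keep)``).
    """
    y0 = np.asarray(y0, float)
    o0 = np.asarray(o0, float)
    keep = (rng.random(y0.shape) < keep_prob).astype(float)
    mean, sd = population_stats.lookup(t0, sex)
    fill = rng.normal(mean, sd)
    seen = keep * o0
    y_tilde = seen * y0 + (1.0 - seen) * fill
    return y_tilde, keep


# ---------------------------------------------------------------------------
# Splitting


def split_cohort(dataset: CohortDataset, fractions=(0.66, 0.17, 0.17),
                 rng=None, *, min_baseline_train=6, min_baseline_test=10):
    """Disjoint source-individual-level train/val/test split.

    All replicas of a source individual share one assignment (no leakage).
    Train/val drop replicas with fewer than ``min_baseline_train`` observed
    baseline variables.  The full test split is kept for population
    comparisons; its ``prediction_mask`` marks the replicas usable for
    individual prediction (>= ``min_baseline_test`` observed baseline
    variables and at least one follow-up visit).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(rng)
    sources = np.unique(dataset.source_id)
    perm = rng.permutation(len(sources))
    n_train = int(round(fractions[0] * len(sources)))
    n_val = int(round(fractions[1] * len(sources)))
    train_src = set(sources[perm[:n_train]])
    val_src = set(sources[perm[n_train:n_train + n_val]])
    assign = np.array([
        0 if s in train_src else (1 if s in val_src else 2)
        for s in dataset.source_id
    ])
    n_obs0 = dataset.o0.sum(axis=1)
    out = []
    for split in (0, 1):
        idx = np.where((assign == split) & (n_obs0 >= min_baseline_train))[0]
        out.append(dataset.subset(idx))
    test_idx = np.where(assign == 2)[0]
    test = dataset.subset(test_idx)
    has_followup = test.visit_mask.sum(axis=1) >= 2
    test.prediction_mask = (test.o0.sum(axis=1) >= min_baseline_test) & has_followup
    out.append(test)
    return tuple(out)


# ---------------------------------------------------------------------------
# Readers / writers


def write_cohort(dataset: CohortDataset, visits_path, individuals_path):
    """Write raw-scale long-format visits table + individuals table."""
    schema = dataset.schema or VariableSchema.identity(dataset.n_vars)
    rows = []
    for m in range(dataset.n_individuals):
        for k in range(dataset.times.shape[1]):
            if not dataset.visit_mask[m, k]:
                continue
            raw = invert_transform(dataset.y[m, k], schema)
            row = {"id": m, "age": dataset.times[m, k]}
            for j, name in enumerate(schema.names):
                row[name] = raw[j] if dataset.o[m, k, j] else np.nan
            rows.append(row)
    pd.DataFrame(rows).to_csv(visits_path, index=False)
    bnames = schema.background_names or [f"u{j}" for j in range(dataset.n_background)]
    irows = []
    for m in range(dataset.n_individuals):
        row = {
            "id": m,
            "source_id": dataset.source_id[m],
            "death_age": dataset.a[m] if dataset.c[m] == 0 else np.nan,
            "censored": int(dataset.c[m]),
            "weight": dataset.s[m],
        }
        for j, name in enumerate(bnames):
            row[name] = dataset.u[m, j] if dataset.u_mask[m, j] else np.nan
        irows.append(row)
    pd.DataFrame(irows).to_csv(individuals_path, index=False)


def read_cohort(visits_path, individuals_path, schema: VariableSchema) -> CohortDataset:
    """Read the two-table format and apply the schema transform."""
    visits = pd.read_csv(visits_path)
    indiv = pd.read_csv(individuals_path)
    bnames = schema.background_names or [
        cname for cname in indiv.columns
        if cname not in ("id", "source_id", "death_age", "censored", "weight")
    ]
    individuals = []
    for _, row in indiv.iterrows():
        vid = row["id"]
        sub = visits[visits["id"] == vid].sort_values("age")
        ages = sub["age"].to_numpy(float)
        raw = sub[schema.names].to_numpy(float)
        o = np.isfinite(raw).astype(float)
        y, o = apply_transform(np.nan_to_num(raw), o, schema)
        u_raw = np.array([row.get(nm, np.nan) for nm in bnames], float)
        u_mask = np.isfinite(u_raw).astype(float)
        death = row.get("death_age", np.nan)
        a, cflag = finalize_outcomes(ages, None if pd.isna(death) else float(death))
        individuals.append({
            "visit_ages": ages, "y": y, "o": o,
            "u": np.nan_to_num(u_raw), "u_mask": u_mask,
            "a": a, "c": cflag,
            "s": float(row.get("weight", 1.0)),
            "source_id": int(row.get("source_id", vid)),
        })
    return CohortDataset.from_individuals(individuals, schema=schema)
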
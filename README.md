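# djin-aging

Joint modelling of high-dimensional aging health trajectories and survival,
with an interpretable interaction network at its core.

## The problem

Longitudinal cohort studies of aging observe dozens of physiological,
functional and molecular variables at irregular ~2-year visits, with heavy
block missingness, and follow individuals until death or loss to
follow-up (often >90% censoring).  Researchers want three things from such
data at once: predicted future health trajectories from a single baseline
visit, calibrated individual survival probabilities, and an interpretable
account of how the health variables drive each other.  Black-box sequence
models deliver the first two; classical linear models the third.  This
package implements a joint model that delivers all three.

## The model

An individual's latent health state **x**(t) ∈ ℝᴺ follows a stochastic
differential equation whose drift couples the variables through a constant
directed matrix **W** (zero diagonal):

    dx_i = ( Σ_j W_ij x_j + f_i(x_i, u, t) ) dt + σ_x,i(x) dB_i(t)

with per-variable networks f_i for the nonlinear diagonal, background
covariates u, and diagonal neural diffusion σ_x.  Visits give masked noisy
observations y_tk ~ N(x(t_k), σ_y²); mortality is a hazard λ(t) computed
by a 2-layer GRU running along the trajectory, with
S(t) = exp(−∫λ dt′); missing baselines are imputed (and synthetic
baselines generated) by a normalizing-flow VAE conditioned on (u, t0).

Inference is stochastic variational: Laplace posteriors per edge W_ij
(prior Laplace(0, 0.05)), Gamma posteriors per measurement noise σ_y,
a posterior SDE with a learned drift correction g as the trajectory
posterior, KL annealing, and Adam with plateau decay.  Edges whose 99%
credible interval excludes zero form the robust network, which is pruned,
signed, and clustered (average linkage) for interpretation.  Everything —
SDE solver, GRU, flows — is one differentiable numpy/autograd program.

Because the cohorts the original analyses used are restricted-access, the
package ships a ground-truth simulator (`djin.synthetic`) that generates
cohorts with the assumed structure — sparse known **W**, mean-reverting
drift, log-linear hazard, ~2-year visits, 30% missingness, ~90% censoring
— so every claim (network recovery, calibration, imputation gain) is
testable against known truth.

## Worked example

Simulate a cohort with a known 6-edge network, fit the model, and inspect
the recovered network:

```python
import numpy as np
from djin import synthetic, dataio
from djin.inference import TrainConfig
from djin.model import DJINModel

rng = np.random.default_rng(11)
truth = synthetic.sample_ground_truth(n_vars=6, sparsity=0.2, rng=rng)
cohort = synthetic.simulate_cohort(truth, M=700, horizon=15.0, dt=0.25, rng=rng)
train, val, test = dataio.split_cohort(cohort, (0.75, 0.15, 0.10), rng=0,
                                       min_baseline_train=4, min_baseline_test=4)

cfg = TrainConfig(epochs=150, horizon=15.0, anneal_xz=(0, 60),
                  anneal_W=(60, 100), seed=0)
results = DJINModel(train, cfg, val_cohort=val).fit()
print(results.summary())

off = ~np.eye(6, dtype=bool)
print("recovery r =",
      np.corrcoef(results.W_bar[off], truth.W_true[off])[0, 1].round(3))
```

Output from this exact script:

```
Joint network-SDE aging model
==============================================
health variables (N):      6
background variables (B):  3
individuals (replicas):    380
epochs run:                150
mean sigma_y (posterior):  0.2539
robust edges (99% CI):     5 / 30
best validation loss:      26.7422

strongest robust edges (source -> target, mean [lo, hi]):
        x4 -> x3       +0.252  [+0.091, +0.413]
        x4 -> x0       +0.203  [+0.080, +0.326]
        x4 -> x5       -0.174  [-0.313, -0.036]
        x1 -> x4       +0.164  [+0.047, +0.282]
        x2 -> x5       -0.156  [-0.298, -0.015]
recovery r = 0.697
```

The summary reports the posterior measurement noise, how many directed
edges survive 99% credible-interval pruning, and the strongest robust
edges with their intervals: each line `xj -> xi  m [lo, hi]` says variable
j's level shifts variable i's yearly drift by m per unit, with the
interval quantifying robustness.  The recovery correlation compares all 30
off-diagonal posterior means with the simulator's true matrix (here the
true network is `x4 -> x0, x4 -> x2, x2 -> x3, x4 -> x3, x1 -> x4` all
positive and `x0 -> x5` negative): three of the five robust edges are true
edges with the correct sign, and the two others attribute the one true
negative influence on x5 to sources correlated with the true one — at this
cohort size the posterior resolves targets more sharply than sources,
and magnitudes are shrunk toward zero by the Laplace prior.  Longer
training on larger cohorts tightens both (see `docs/methods.md`).

Prediction, generation and evaluation hang off the results object:
`results.predict(test)` returns trajectory means and survival curves
(scored by `djin.evaluate.c_index_td`, `integrated_brier`,
`d_calibration`, `rmse`), `results.generate_population(test)` samples
synthetic individuals from (u, t0) alone, and
`results.impute_baseline(test)` multiply-imputes missing baselines.
Elastic-net Cox, linear trajectory, and MICE random-forest baselines live
in `djin.baselines`.  A `djin` command-line tool wraps the same steps
(`djin simulate`, `prep`, `train`, `trajectories`, `survival`, `impute`,
`evaluate`, `baselines`).

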
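"""Variational objective: likelihood pieces, KL terms, annealing, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from djin import dataio, inference, mortality, synthetic
from djin.inference import (TrainConfig, anneal, elbo_loss, kl_gamma,
                            kl_laplace, kl_latent, obs_loglik, path_penalty,
                            prepare_batch, sample_noise, survival_loglik)

LOG2PI = np.log(2 * np.pi)


class TestObsLoglik:
    def test_all_masked_is_zero(self):
        rng = np.random.default_rng(0)
        y, x = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert obs_loglik(y, np.zeros((4, 3)), x, 0.5) == 0.0

    def test_single_observed_residual_zero(self):
        y = np.array([[1.3]])
        ll = obs_loglik(y, np.ones((1, 1)), y, 1.0)
        assert ll == pytest.approx(-0.5 * LOG2PI)

    def test_unobserved_entry_changes_nothing(self):
        y = np.array([[1.0, 99.0]])
        o = np.array([[1.0, 0.0]])
        x = np.array([[1.0, 0.0]])
        assert obs_loglik(y, o, x, 1.0) == pytest.approx(-0.5 * LOG2PI)

    def test_nonpositive_sigma_errors(self):
        with pytest.raises(ValueError):
            obs_loglik(np.zeros((1, 1)), np.ones((1, 1)),
                       np.zeros((1, 1)), 0.0)


class TestSurvivalLoglik:
    def test_censored_unit_survival_contributes_zero(self):
        times = np.arange(0, 10.5, 0.5)
        S = np.ones_like(times)
        lam = np.zeros_like(times)
        ll = survival_loglik(S, lam, times, 8.0, 1)
        assert abs(ll) < 1e-4          # only the 1e-6 clamp remains

    def test_constant_hazard_matches_hand_integral(self):
        lam0 = 0.1
        times = np.arange(0, 10.0005, 0.001)
        lam = np.full_like(times, lam0)
        S = np.exp(-lam0 * times)
        # censored at a=8: int_0^8 log S dt = -lam0 a^2/2
        ll = survival_loglik(S, lam, times, 8.0, 1)
        assert abs(ll - (-lam0 * 8.0 ** 2 / 2)) < 1e-6
        # uncensored at a=5 with a 5-year window
        i2 = quad(lambda t: np.log(1 - np.clip(np.exp(-lam0 * t), 1e-6,
                                               1 - 1e-6)), 5.0, 10.0)[0]
        exact = np.log(lam0) - lam0 * 5.0 + i2
        ll = survival_loglik(S, lam, times, 5.0, 0, a_max_window=5.0)
        assert abs(ll - exact) < 1e-6

    def test_survival_near_one_after_death_heavily_penalized(self):
        times = np.arange(0, 10.5, 0.5)
        S = np.ones_like(times)
        lam = np.full_like(times, 0.1)
        ll = survival_loglik(S, lam, times, 2.0, 0)
        assert np.isfinite(ll) and ll < -20.0   # log(1-S) under the clamp


class TestPathPenalty:
    def test_zero_when_posterior_matches_prior(self):
        rng = np.random.default_rng(0)
        T, n = 8, 3
        paths = rng.normal(size=(T, n))
        W = rng.normal(0, 0.2, (n, n))
        times = np.arange(T) * 0.5
        pen = path_penalty(paths, times, W, W, np.zeros((T, n)),
                           np.ones((T, n)))
        assert pen == 0.0

    def test_constant_mismatch_hand_integral(self):
        T, n = 11, 2
        times = np.arange(T) * 1.0
        paths = np.ones((T, n))            # constant state
        W = np.zeros((n, n))
        m = np.array([0.3, -0.4])          # constant correction mismatch
        g = np.tile(m, (T, 1))
        pen = path_penalty(paths, times, W, W, g, np.ones((T, n)))
        assert pen == pytest.approx(-0.5 * np.sum(m ** 2) * 10.0)

    def test_always_nonpositive(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            T, n = 6, 3
            pen = path_penalty(
                rng.normal(size=(T, n)), np.arange(T) * 0.5,
                rng.normal(0, 0.3, (n, n)), rng.normal(0, 0.3, (n, n)),
                rng.normal(size=(T, n)), rng.uniform(0.5, 2, (T, n)))
            assert pen <= 0.0

    def test_zero_sigma_errors(self):
        with pytest.raises(ValueError):
            path_penalty(np.ones((3, 2)), np.arange(3.0),
                         np.zeros((2, 2)), np.zeros((2, 2)),
                         np.zeros((3, 2)), np.zeros((3, 2)))


class TestKL:
    def test_laplace_identical_distributions_zero(self):
        assert kl_laplace(np.zeros(4), np.full(4, 0.05), 0.05) == 0.0

    def test_laplace_matches_quadrature(self):
        m, b, s = 0.1, 0.05, 0.05
        kl = kl_laplace(np.array([m]), np.array([b]), s)
        pdf_q = lambda x: np.exp(-abs(x - m) / b) / (2 * b)
        integrand = lambda x: pdf_q(x) * ((-abs(x - m) / b - np.log(2 * b))
                                          - (-abs(x) / s - np.log(2 * s)))
        ref = quad(integrand, -2, 2, limit=400)[0]
        assert abs(kl - ref) < 1e-6

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(-2, 2), st.floats(0.01, 2))
    def test_laplace_nonnegative(self, m, b):
        assert kl_laplace(np.array([m]), np.array([b]), 0.05) >= -1e-12

    def test_laplace_nonpositive_scale_errors(self):
        with pytest.raises(ValueError):
            kl_laplace(np.zeros(2), np.zeros(2))

    def test_gamma_identical_distributions_zero(self):
        prior = (1.0, 1.0 / 25000.0)
        assert kl_gamma(np.array([1.0]), np.array([prior[1]]), prior) \
            == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("a,b", [(2.0, 3.0), (25.0, 250.0), (1.5, 0.5)])
    def test_gamma_matches_quadrature(self, a, b):
        a0, b0 = 2.0, 1.0
        kl = kl_gamma(np.array([a]), np.array([b]), (a0, b0))
        f = lambda x: gamma_dist.pdf(x, a, scale=1 / b) * (
            gamma_dist.logpdf(x, a, scale=1 / b)
            - gamma_dist.logpdf(x, a0, scale=1 / b0))
        ref = quad(f, 0, np.inf, limit=400)[0]
        assert abs(kl - ref) < 1e-6

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0.1, 20), st.floats(0.1, 20))
    def test_gamma_nonnegative(self, a, b):
        assert kl_gamma(np.array([a]), np.array([b]), (2.0, 1.0)) >= -1e-10

    def test_latent_standard_normal_identity_flows_zero(self):
        assert np.allclose(
            kl_latent(np.zeros((2, 3)), np.ones((2, 3)), np.zeros(2)), 0.0)

    def test_latent_unit_mean_half(self):
        kl = kl_latent(np.array([[1.0]]), np.array([[1.0]]), np.zeros(1))
        assert kl[0] == pytest.approx(0.5)

    def test_latent_gaussian_part_nonnegative(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(50, 4))
        sig = rng.uniform(0.1, 3.0, (50, 4))
        assert np.all(kl_latent(mu, sig, np.zeros(50)) >= -1e-12)


class TestAnneal:
    @pytest.mark.parametrize("epoch,expected", [
        (0, (0.0, 0.0)), (150, (0.5, 0.0)), (300, (1.0, 0.0)),
        (400, (1.0, 0.5)), (500, (1.0, 1.0)), (900, (1.0, 1.0)),
    ])
    def test_default_schedule(self, epoch, expected):
        assert anneal(epoch, TrainConfig()) == pytest.approx(expected)

    def test_misordered_windows_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(anneal_xz=(0, 400), anneal_W=(300, 500))


def _tiny_training_setup(M=40, seed=0):
    rng = np.random.default_rng(seed)
    truth = synthetic.sample_ground_truth(3, 0.2, rng)
    cohort = synthetic.simulate_cohort(truth, M, 8.0, 0.25, rng)
    cfg = TrainConfig(epochs=0, batch_size=500, horizon=8.0,
                      anneal_xz=(0, 10), anneal_W=(10, 20), seed=seed)
    return cohort, cfg


class TestElbo:
    def test_masked_out_and_matched_posteriors_give_zero_loss(self):
        cohort, cfg = _tiny_training_setup()
        state = inference.init_state(3, 3, cfg, np.random.default_rng(0))
        p = state.params
        # q = p everywhere: zero network posterior at the prior scale,
        # Gamma posterior equal to its prior, unit Gaussian latent
        p["W_bar"] = np.zeros((3, 3))
        p["log_b"] = np.full((3, 3), np.log(cfg.prior_w_scale))
        p["log_alpha"] = np.zeros(3)
        p["log_beta"] = np.full(3, np.log(cfg.prior_gamma[1]))
        for key in ("enc_out", "enc_gamma"):
            for layer in p["imp"][key]:
                layer["W"] = np.zeros_like(layer["W"])
                layer["b"] = np.zeros_like(layer["b"])
        for layer in p["dyn"]["g"]:
            layer["W"] = np.zeros_like(layer["W"])
            layer["b"] = np.zeros_like(layer["b"])
        p["haz"]["head"][-1]["W"] = np.zeros_like(p["haz"]["head"][-1]["W"])
        p["haz"]["head_bias"] = np.array([-60.0])     # hazard ~ 0
        batch = prepare_batch(cohort, cfg)
        batch["o0"] = np.zeros_like(batch["o0"])
        batch["o"] = np.zeros_like(batch["o"])
        batch["o_enc"] = np.zeros_like(batch["o_enc"])
        batch["c"] = np.ones_like(batch["c"])
        batch["cens_w"] *= 0.0
        noise = sample_noise(batch, cfg, np.random.default_rng(1))
        noise["U_w"] *= 0.0            # posterior W sample = W_bar
        loss = inference.getval(elbo_loss(p, batch, noise, (1.0, 1.0), cfg))
        assert abs(loss) < 1e-3

    def test_weight_linearity(self):
        # the unnormalized objective is linear in each sample weight
        cohort, cfg = _tiny_training_setup(M=10)
        state = inference.init_state(3, 3, cfg, np.random.default_rng(0))
        batch = prepare_batch(cohort, cfg)
        noise = sample_noise(batch, cfg, np.random.default_rng(2))

        def U(weights):
            b = dict(batch)
            b["s"] = weights
            loss = inference.getval(elbo_loss(state.params, b, noise,
                                              (0.5, 0.0), cfg))
            return -loss * weights.sum()

        s = batch["s"].copy()
        s2 = s.copy(); s2[0] *= 2.0
        s3 = s.copy(); s3[0] *= 3.0
        d21 = U(s2) - U(s)
        d32 = U(s3) - U(s2)
        assert d21 == pytest.approx(d32, rel=1e-9)
        assert abs(d21) > 0

    def test_elbo_wrapper_finite(self):
        cohort, cfg = _tiny_training_setup(M=15)
        state = inference.init_state(3, 3, cfg, np.random.default_rng(0))
        batch = prepare_batch(cohort, cfg)
        val = inference.elbo(batch, state, (0.5, 0.5),
                             np.random.default_rng(0))
        assert np.isfinite(val)


class TestTrain:
    def test_zero_epochs_returns_initialized_state(self):
        cohort, cfg = _tiny_training_setup()
        state = inference.train(cohort, cfg)
        ref = inference.init_state(3, 3, cfg, np.random.default_rng(cfg.seed))
        assert np.array_equal(state.params["W_bar"], ref.params["W_bar"])
        assert state.history == []

    def test_loss_decreases_and_checkpoint_improves(self):
        from dataclasses import replace
        cohort, cfg = _tiny_training_setup(M=60, seed=3)
        cfg = replace(cfg, epochs=30)
        tr = cohort.subset(np.arange(45))
        va = cohort.subset(np.arange(45, 60))
        state = inference.train(tr, cfg, val_cohort=va)
        hist = [h for h in state.history if "train_loss" in h]
        early = np.mean([h["train_loss"] for h in hist[:5]])
        late = np.mean([h["train_loss"] for h in hist[-5:]])
        assert late < early
        done = state.history[-1]
        assert done["best_val"] <= hist[0]["val_loss"]

    def test_seed_reproducible(self):
        from dataclasses import replace
        cohort, cfg = _tiny_training_setup(M=25, seed=4)
        cfg = replace(cfg, epochs=4)
        a = inference.train(cohort, cfg)
        b = inference.train(cohort, cfg)
        assert np.array_equal(a.params["W_bar"], b.params["W_bar"])
        assert np.array_equal(a.params["haz"]["head"][0]["W"],
                              b.params["haz"]["head"][0]["W"])

    def test_latent_mode_trains(self):
        from dataclasses import replace
        cohort, cfg = _tiny_training_setup(M=25, seed=5)
        cfg = replace(cfg, epochs=3, mode="latent", latent_dim=4)
        state = inference.train(cohort, cfg)
        hist = [h for h in state.history if "train_loss" in h]
        assert len(hist) == 3
        assert all(np.isfinite(h["train_loss"]) for h in hist)

    def test_latent_summary_mode_trains(self):
        from dataclasses import replace
        cohort, cfg = _tiny_training_setup(M=25, seed=6)
        cfg = replace(cfg, epochs=2, mode="latent_summary", latent_dim=1)
        state = inference.train(cohort, cfg)
        assert len([h for h in state.history if "train_loss" in h]) == 2
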
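"""Evaluation metrics against hand calculations and brute-force oracles."""

import numpy as np
import pytest

from djin import evaluate
from djin.dataio import VariableSchema
from djin.evaluate import (PredictionSet, brier, c_index_td, censoring_km,
                           d_calibration, integrated_brier,
                           population_discriminator, rmse)


def _pred_from_curves(offsets, t0, surv, a, c, s=None):
    M, T = surv.shape
    return PredictionSet(
        offsets=np.asarray(offsets, float), t0=np.asarray(t0, float),
        traj=np.zeros((M, T, 1)), surv=np.asarray(surv, float),
        times=np.full((M, 1), np.nan), y=np.zeros((M, 1, 1)),
        o=np.zeros((M, 1, 1)), a=np.asarray(a, float),
        c=np.asarray(c, int),
        s=np.ones(M) if s is None else np.asarray(s, float))


def _exp_curves(offsets, t0, lams):
    return np.exp(-np.outer(lams, offsets))


# ---------------------------------------------------------------------------
# RMSE


class TestRmse:
    def test_perfect_prediction_zero(self):
        obs = np.random.default_rng(0).normal(size=(5, 3))
        assert rmse(obs, obs, np.ones((5, 3)), np.ones(5)) == 0.0

    def test_hand_arithmetic(self):
        # errors 1 and 3 with equal weights -> sqrt((1+9)/2) = sqrt(5)
        pred = np.array([[1.0], [3.0]])
        obs = np.zeros((2, 1))
        out = rmse(pred, obs, np.ones((2, 1)), np.ones(2))
        assert out == pytest.approx(np.sqrt(5.0))

    def test_raw_scale_inversion(self):
        schema = VariableSchema(names=["v"], log_flags=[True],
                                train_mean=[0.0], train_sd=[1.0])
        # transformed error 0 but raw error exp(1)-exp(0) when shifted
        pred = np.array([[1.0]])
        obs = np.array([[0.0]])
        out = rmse(pred, obs, np.ones((1, 1)), np.ones(1), schema=schema)
        assert out == pytest.approx(np.e - 1.0)

    def test_duplication_with_halved_weights_invariant(self):
        rng = np.random.default_rng(1)
        pred, obs = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        mask = np.ones((4, 2))
        r1 = rmse(pred, obs, mask, np.ones(4))
        r2 = rmse(np.vstack([pred, pred]), np.vstack([obs, obs]),
                  np.vstack([mask, mask]), np.full(8, 0.5))
        assert r1 == pytest.approx(r2)

    def test_nothing_observed_flagged(self):
        assert np.isnan(rmse(np.ones((2, 1)), np.ones((2, 1)),
                             np.zeros((2, 1)), np.ones(2)))

    def test_matched_mean_predictor_relative_score_is_one(self, cohort6):
        means = evaluate.AgeSexMeans(cohort6)
        preds, obs, mask = [], [], []
        for m in range(50):
            k = int(cohort6.visit_mask[m].sum())
            ages = cohort6.times[m, :k]
            preds.append(means.predict(ages, np.full(k, cohort6.u[m, 0])))
            obs.append(cohort6.y[m, :k])
            mask.append(cohort6.o[m, :k])
        preds, obs, mask = map(np.concatenate, (preds, obs, mask))
        r = rmse(preds, obs, mask, np.ones(len(preds)))
        assert r / r == 1.0 and r > 0


# ---------------------------------------------------------------------------
# time-dependent C-index


def _cindex_brute(pred):
    """Direct double-loop transcription of the pairwise definition."""
    num = den = 0.0
    M = len(pred.a)
    for m1 in range(M):
        for m2 in range(M):
            if m1 == m2:
                continue
            if pred.c[m1] == 0 and pred.a[m1] < pred.a[m2]:
                w = pred.s[m1] * pred.s[m2]
                den += w
                if pred.surv_at(m1, pred.a[m1]) < pred.surv_at(m2, pred.a[m1]):
                    num += w
    return num / den if den else np.nan


class TestCIndex:
    def test_perfectly_anti_ordered_curves_score_one(self):
        offsets = np.arange(0, 10.5, 0.5)
        # higher hazard <-> earlier death: every comparable pair concordant
        lams = np.array([0.5, 0.3, 0.1])
        a = np.array([2.0, 4.0, 8.0])
        pred = _pred_from_curves(offsets, np.zeros(3),
                                 _exp_curves(offsets, 0, lams), a,
                                 np.zeros(3))
        assert c_index_td(pred) == 1.0

    def test_curves_ordered_with_death_ages_score_zero(self):
        offsets = np.arange(0, 10.5, 0.5)
        lams = np.array([0.1, 0.3, 0.5])     # earliest death, highest S
        a = np.array([2.0, 4.0, 8.0])
        pred = _pred_from_curves(offsets, np.zeros(3),
                                 _exp_curves(offsets, 0, lams), a,
                                 np.zeros(3))
        assert c_index_td(pred) == 0.0

    def test_mixed_censoring_toy_matches_enumeration(self):
        offsets = np.arange(0, 12.5, 0.5)
        lams = np.array([0.4, 0.15, 0.25, 0.05])
        a = np.array([3.0, 5.0, 5.5, 9.0])
        c = np.array([0, 1, 0, 1])
        s = np.array([1.0, 0.5, 0.5, 1.0])
        pred = _pred_from_curves(offsets, np.zeros(4),
                                 _exp_curves(offsets, 0, lams), a, c, s)
        assert c_index_td(pred) == pytest.approx(_cindex_brute(pred))

    def test_no_comparable_pairs_flagged(self):
        offsets = np.arange(0, 5.5, 0.5)
        pred = _pred_from_curves(offsets, np.zeros(2),
                                 _exp_curves(offsets, 0, [0.1, 0.2]),
                                 [3.0, 4.0], [1, 1])
        assert np.isnan(c_index_td(pred))

    def test_random_small_datasets_match_brute_force(self):
        rng = np.random.default_rng(7)
        offsets = np.arange(0, 15.5, 0.5)
        for _ in range(40):
            M = rng.integers(2, 7)
            lams = rng.uniform(0.02, 0.6, M)
            a = rng.uniform(1.0, 14.0, M)
            c = rng.integers(0, 2, M)
            s = rng.uniform(0.2, 1.0, M)
            pred = _pred_from_curves(offsets, np.zeros(M),
                                     _exp_curves(offsets, 0, lams), a, c, s)
            got = c_index_td(pred)
            want = _cindex_brute(pred)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)


# ---------------------------------------------------------------------------
# censoring KM and Brier


class TestCensoringKM:
    def test_no_censoring_G_is_one(self):
        G = censoring_km([2.0, 3.0, 4.0], [0, 0, 0])
        assert np.allclose(G(np.array([1.0, 3.5, 9.0])), 1.0)

    def test_all_censored_at_one_time_steps_to_zero(self):
        G = censoring_km([5.0, 5.0, 5.0], [1, 1, 1])
        assert G(4.9) == 1.0 and G(5.0) == 0.0

    def test_hand_product_limit(self):
        # events (censorings) at 2 and 6; deaths at 3, 4 act as censorings
        a = np.array([2.0, 3.0, 4.0, 6.0, 7.0])
        c = np.array([1, 0, 0, 1, 0])
        G = censoring_km(a, c)
        assert G(2.0) == pytest.approx(1 - 1 / 5)          # 4/5
        assert G(6.0) == pytest.approx((4 / 5) * (1 - 1 / 2))  # risk set {6,7}
        assert G(1.9) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            censoring_km([], [])


class TestBrier:
    def test_perfect_step_predictions_zero(self):
        offsets = np.arange(0, 10.5, 0.5)
        a = np.array([3.0, 7.0])
        surv = np.array([(offsets < a[0]).astype(float),
                         (offsets < a[1]).astype(float)])
        pred = _pred_from_curves(offsets, np.zeros(2), surv, a, np.zeros(2))
        for t in (1.0, 3.5, 6.0, 8.0):
            assert brier(pred, t) == pytest.approx(0.0)

    def test_half_survival_all_alive_quarter(self):
        offsets = np.arange(0, 10.5, 0.5)
        surv = np.full((4, len(offsets)), 0.5)
        pred = _pred_from_curves(offsets, np.zeros(4), surv,
                                 np.full(4, 9.0), np.zeros(4))
        assert brier(pred, 5.0) == pytest.approx(0.25)

    def test_censored_toy_matches_hand_sum(self):
        offsets = np.arange(0, 10.5, 0.5)
        lams = np.array([0.2, 0.1, 0.3])
        a = np.array([2.0, 5.0, 8.0])
        c = np.array([0, 1, 0])
        pred = _pred_from_curves(offsets, np.zeros(3),
                                 _exp_curves(offsets, 0, lams), a, c)
        G = censoring_km(a, c)
        t = 4.0
        # individual 0 dead by 4: S0(4)^2/G(2); 1 and 2 alive: (1-S)^2/G(4)
        hand = (np.exp(-0.2 * 4) ** 2 / G(2.0)
                + (1 - np.exp(-0.1 * 4)) ** 2 / G(4.0)
                + (1 - np.exp(-0.3 * 4)) ** 2 / G(4.0)) / 3
        assert brier(pred, t) == pytest.approx(hand)

    def test_integrated_brier_perfect_predictor_zero(self):
        offsets = np.arange(0, 10.5, 0.5)
        a = np.array([3.0, 5.0, 7.0])
        surv = np.array([(offsets < ai).astype(float) for ai in a])
        pred = _pred_from_curves(offsets, np.zeros(3), surv, a, np.zeros(3))
        assert integrated_brier(pred) == pytest.approx(0.0)

    def test_integrated_brier_duplication_invariance(self):
        offsets = np.arange(0, 10.5, 0.5)
        lams = np.array([0.2, 0.1, 0.35, 0.05])
        a = np.array([2.0, 4.0, 6.0, 9.0])
        c = np.array([0, 0, 1, 0])
        surv = _exp_curves(offsets, 0, lams)
        p1 = _pred_from_curves(offsets, np.zeros(4), surv, a, c)
        p2 = _pred_from_curves(offsets, np.zeros(8), np.vstack([surv, surv]),
                               np.tile(a, 2), np.tile(c, 2),
                               np.full(8, 0.5))
        assert integrated_brier(p1) == pytest.approx(integrated_brier(p2))


# ---------------------------------------------------------------------------
# D-calibration


class TestDCalibration:
    def test_exactly_uniform_counts(self):
        S = np.linspace(0.05, 0.95, 10)      # one per decile
        counts, chi2, p = d_calibration(S, np.zeros(10, int))
        assert np.allclose(counts, 1.0)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_pearson_statistic(self):
        # counts [20,0,10,...,10] over n=100 -> chi2 = (100+100)/10 = 20
        S = np.concatenate([
            np.linspace(0.001, 0.099, 20),              # 20 in decile 0
            np.linspace(0.201, 0.299, 10),
            np.linspace(0.301, 0.399, 10),
            np.linspace(0.401, 0.499, 10),
            np.linspace(0.501, 0.599, 10),
            np.linspace(0.601, 0.699, 10),
            np.linspace(0.701, 0.799, 10),
            np.linspace(0.801, 0.899, 10),
            np.linspace(0.101, 0.199, 0),           # empty decile 1
            np.linspace(0.901, 0.989, 10),
        ])
        counts, chi2, p = d_calibration(S, np.zeros(len(S), int))
        assert len(S) == 100
        assert chi2 == pytest.approx(20.0)

    def test_censored_mass_spread_below_quantile(self):
        # one censored individual with S(a) = 0.5: half a unit in each of
        # the five deciles below 0.5
        S = np.array([0.5])
        counts, _, _ = d_calibration(np.tile(S, 10), np.ones(10, int))
        assert np.allclose(counts[:5], 2.0)
        assert np.allclose(counts[5:], 0.0)

    def test_pit_property_on_simulated_outcomes(self):
        # death ages drawn from the curves themselves are calibrated
        rng = np.random.default_rng(0)
        offsets = np.linspace(0, 60, 601)
        pvals = []
        for _ in range(40):
            lams = rng.uniform(0.05, 0.4, 120)
            surv = _exp_curves(offsets, 0, lams)
            a, c = evaluate.sample_outcomes_from_curves(
                np.tile(offsets, (120, 1)), surv, rng)
            S_at = np.array([np.interp(a[m], offsets, surv[m])
                             for m in range(120)])
            _, _, p = d_calibration(S_at, c)
            pvals.append(p)
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_fewer_than_bins_errors(self):
        with pytest.raises(ValueError):
            d_calibration(np.array([0.5, 0.4]), np.zeros(2, int))


# ---------------------------------------------------------------------------
# population discriminator


class TestDiscriminator:
    def test_identical_populations_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 5))
        acc = population_discriminator(X[:1000], X[1000:], rng)
        se = np.sqrt(0.25 / 600)
        assert abs(acc - 0.5) < 4 * se

    def test_shifted_population_separable(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1000, 5))
        Y = rng.normal(size=(1000, 5))
        Y[:, 2] += 5.0
        acc = population_discriminator(X, Y, rng)
        assert acc > 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(600, 3))
        Y = rng.normal(size=(600, 3)) + 0.3
        a = population_discriminator(X, Y, np.random.default_rng(5))
        b = population_discriminator(X, Y, np.random.default_rng(5))
        assert a == b

    def test_extreme_imbalance_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="imbalance"):
            population_discriminator(rng.normal(size=(1000, 2)),
                                     rng.normal(size=(10, 2)), rng)
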
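import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpkf.filter import (
    ModeState,
    kalman_gain,
    mode_loglik,
    predict_mode,
    run_filter,
    update_mode,
)
from dpkf.params import Hyperparameters

from oracles import chain_joint_gaussian, gauss_logpdf, textbook_kf


def hp1d(**kw):
    base = dict(alpha=1.0, beta=0.0, q=1.0, r=1.0, v=1.0, m0=0.0, c=1000.0, n_dims=1)
    base.update(kw)
    return Hyperparameters(**base)


class TestPredictMode:
    def test_one_diffusion_step(self):
        state = ModeState(mean=[3.0], var=[4.0], count=2, last_active=4)
        m, s = predict_mode(state, 5, hp1d(q=2.0))
        assert m[0] == 3.0 and s[0] == 6.0

    def test_dormant_mode_variance_grows_linearly(self):
        state = ModeState(mean=[3.0], var=[4.0], count=2, last_active=1)
        m, s = predict_mode(state, 6, hp1d(q=2.0))
        assert m[0] == 3.0 and s[0] == 4.0 + 5 * 2.0

    def test_zero_diffusion_keeps_variance(self):
        state = ModeState(mean=[3.0], var=[4.0], count=2, last_active=1)
        for now in (2, 7):
            _, s = predict_mode(state, now, hp1d(q=0.0))
            assert s[0] == 4.0

    def test_rejects_nonpositive_gap(self):
        state = ModeState(mean=[0.0], var=[1.0], count=1, last_active=5)
        with pytest.raises(ValueError):
            predict_mode(state, 5, hp1d())

    def test_virtual_new_mode_is_base_measure(self):
        m, s = predict_mode(None, 3, hp1d(m0=7.0, c=11.0))
        assert m[0] == 7.0 and s[0] == 11.0


class TestKalmanGain:
    def test_symmetric_case(self):
        assert kalman_gain(np.array([2.0]), np.array([2.0]))[0] == 0.5

    def test_new_mode_prior_gain(self):
        eta = kalman_gain(np.array([1000.0]), np.array([20.0]))[0]
        assert abs(eta - 1000 / 1020) < 1e-12

    def test_noise_dominated_limit(self):
        assert kalman_gain(np.array([1.0]), np.array([1e12]))[0] < 1e-11

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            kalman_gain(np.array([0.0]), np.array([1.0]))


class TestUpdateMode:
    def test_first_observation_of_a_new_mode(self):
        hp = hp1d(m0=50.0, c=1000.0, r=20.0)
        st_ = update_mode(None, np.array([80.0]), 1, hp)
        assert abs(st_.mean[0] - (50 + 1000 / 1020 * 30)) < 1e-9  # 79.4117...
        assert abs(st_.var[0] - (1 - 1000 / 1020) * 1000) < 1e-9  # 19.6078...
        assert st_.count == 1 and st_.last_active == 1

    def test_confirming_observation_shrinks_variance_only(self):
        hp = hp1d(q=0.0, r=2.0)
        state = ModeState(mean=[5.0], var=[3.0], count=1, last_active=1)
        new = update_mode(state, np.array([5.0]), 2, hp)
        assert new.mean[0] == 5.0
        assert abs(new.var[0] - (1 - 3 / 5) * 3) < 1e-12
        assert state.count == 1  # input not mutated

    def test_repeated_constant_signal_converges(self):
        hp = hp1d(q=0.0, r=1.0, m0=0.0, c=100.0)
        state = None
        y = np.array([10.0])
        errs = []
        for t in range(1, 30):
            state = update_mode(state, y, t, hp)
            errs.append(abs(state.mean[0] - 10.0))
        assert all(b <= a for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-2 and state.var[0] < 0.05

    def test_rejects_nonfinite_observation(self):
        with pytest.raises(ValueError):
            update_mode(None, np.array([np.nan]), 1, hp1d())


class TestModeLoglik:
    def test_hand_evaluated_density(self):
        hp = hp1d(q=0.0, r=1.0)
        state = ModeState(mean=[0.0], var=[1.0], count=1, last_active=1)
        ll = mode_loglik(state, np.array([0.0]), 2, hp)
        assert abs(ll - (-0.5 * math.log(4 * math.pi))) < 1e-12

    def test_new_mode_depends_weakly_on_observation_location(self):
        hp = hp1d(m0=0.0, c=1000.0, r=1.0)
        center = mode_loglik(None, np.array([0.0]), 1, hp)
        for y in (10.0, -10.0):
            assert abs(mode_loglik(None, np.array([y]), 1, hp) - center) < 0.05

    def test_dormant_modes_tolerate_errors_better(self):
        """At a fixed error larger than the predictive sd, the density of
        an old mode grows with the dormancy gap."""
        hp = hp1d(q=0.5, r=1.0)
        err = 6.0
        lls = []
        for last in (9, 5, 1):  # gaps 1, 5, 9
            state = ModeState(mean=[0.0], var=[1.0], count=1, last_active=last)
            lls.append(mode_loglik(state, np.array([err]), 10, hp))
        assert lls[0] < lls[1] < lls[2]


class TestRunFilter:
    def test_first_trial_opens_mode_one_with_certainty(self):
        tr = run_filter(np.array([[3.0]]), hp1d())
        assert tr.assignments[0] == 1
        np.testing.assert_allclose(tr.mode_probs[0], [1.0])

    def test_alpha_zero_equals_textbook_kalman_filter(self):
        rng = np.random.default_rng(123)
        for lam, q in ((1.0, 0.7), (0.9, 0.3)):
            y = rng.normal(0, 5, size=100)
            hp = hp1d(alpha=0.0, q=q, r=2.0, decay=lam, m0=1.0, c=50.0)
            tr = run_filter(y[:, None], hp)
            pred, _, filt, _ = textbook_kf(y, q=q, r=2.0, lam=lam, m0=1.0, c=50.0)
            assert tr.n_modes == 1
            np.testing.assert_allclose(tr.predicted_obs[:, 0], pred, atol=1e-10)
            np.testing.assert_allclose(tr.modes[0].mean[0], filt[-1], atol=1e-10)

    def test_alpha_zero_q_zero_is_shrinking_running_mean(self):
        y = np.array([4.0, 6.0, 5.0, 7.0])
        hp = hp1d(alpha=0.0, q=0.0, r=2.0, m0=0.0, c=100.0)
        tr = run_filter(y[:, None], hp)
        m, P = 0.0, 100.0
        for t in range(4):
            assert abs(tr.predicted_obs[t, 0] - m) < 1e-12
            gain = P / (P + 2.0)
            m, P = m + gain * (y[t] - m), (1 - gain) * P

    def test_jump_triggers_new_mode_and_catch_up(self):
        hp = hp1d(alpha=1.0, q=0.2, r=1.0)
        y = np.concatenate([np.linspace(0, 5, 11), np.linspace(25, 27, 5)])
        tr = run_filter(y[:, None], hp)
        assert np.all(tr.assignments[:11] == 1)
        assert tr.assignments[11] == 2  # jump of 20 >> sqrt(pred var + r)
        assert abs(tr.assigned_pred[12, 0] - y[11]) < 2.0  # next prediction caught up

    def test_posteriors_normalized_and_consistent(self):
        rng = np.random.default_rng(5)
        hp = hp1d(alpha=2.0, beta=1.0, q=0.5, r=1.0)
        tr = run_filter(rng.normal(0, 8, size=(60, 1)), hp)
        for t, p in enumerate(tr.mode_probs):
            assert abs(p.sum() - 1.0) < 1e-12
            assert tr.assignments[t] == np.argmax(p) + 1
        assert tr.n_modes == len(set(tr.assignments))

    def test_no_underflow_for_huge_errors(self):
        hp = hp1d(alpha=1.0, q=0.1, r=1.0)
        y = np.array([[0.0], [1e4]])
        tr = run_filter(y, hp)
        assert np.all(np.isfinite([p.sum() for p in tr.mode_probs]))
        assert tr.assignments[1] == 2

    def test_new_mode_probability_monotone_in_alpha_and_beta(self):
        """Probability of opening a new mode on a fixed surprising
        observation: nondecreasing in alpha, nonincreasing in beta."""
        y = np.concatenate([np.zeros(5), [8.0]])[:, None]

        def p_new(alpha, beta):
            tr = run_filter(y, hp1d(alpha=alpha, beta=beta, q=0.1, r=1.0))
            return tr.mode_probs[5][-1]

        alphas = [0.1, 0.5, 1.0, 3.0]
        ps = [p_new(a, 0.0) for a in alphas]
        assert all(b >= a for a, b in zip(ps, ps[1:]))
        betas = [0.0, 1.0, 5.0, 20.0]
        ps = [p_new(1.0, b) for b in betas]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_per_mode_moments_equal_exact_conditioning_on_partition(self):
        """Conditional on the realized partition, each mode's filtered
        mean/variance must equal exact Gaussian conditioning on that
        mode's observation subsequence (brute-force joint oracle)."""
        rng = np.random.default_rng(17)
        hp = hp1d(alpha=1.5, beta=0.5, q=0.8, r=1.3, decay=0.95, m0=0.5, c=30.0)
        for _ in range(10):
            y = rng.normal(0, 6, size=(6, 1))
            tr = run_filter(y, hp)
            for mode in range(1, tr.n_modes + 1):
                chain = tr.chain(mode)
                filt, _ = chain_joint_gaussian(
                    list(chain), y[chain - 1, 0], q=0.8, r=1.3, lam=0.95, m0=0.5, c=30.0
                )
                assert abs(tr.modes[mode - 1].mean[0] - filt[-1]) < 1e-8

    def test_determinism(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 5, size=(40, 2))
        hp = Hyperparameters(alpha=1.0, beta=2.0, q=[0.5, 1.0], r=[1.0, 2.0], v=1.0, m0=0.0, n_dims=2)
        a, b = run_filter(y, hp), run_filter(y, hp)
        np.testing.assert_array_equal(a.predicted_obs, b.predicted_obs)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_rejects_empty_and_mismatched_input(self):
        with pytest.raises(ValueError):
            run_filter(np.empty((0, 1)), hp1d())
        with pytest.raises(ValueError):
            run_filter(np.zeros((5, 3)), hp1d())

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_mixture_prediction_within_candidate_hull(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 5, size=(15, 1))
        hp = hp1d(alpha=1.0, beta=1.0, q=0.5, r=1.0)
        tr = run_filter(y, hp)
        # prediction is a convex combination of mode means and m0
        for t in range(1, 15):
            cand = np.append(y[:t, 0], 0.0)  # mode means live between obs extremes and m0
            assert tr.predicted_obs[t, 0] <= max(cand.max(), 0.0) + 1e-9
            assert tr.predicted_obs[t, 0] >= min(cand.min(), 0.0) - 1e-9


def test_loglik_matches_explicit_gaussian():
    hp = hp1d(q=0.3, r=0.7)
    state = ModeState(mean=[1.2], var=[0.4], count=1, last_active=3)
    ll = mode_loglik(state, np.array([2.0]), 5, hp)
    assert abs(ll - gauss_logpdf(2.0, 1.2, 0.4 + 2 * 0.3 + 0.7)) < 1e-12
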
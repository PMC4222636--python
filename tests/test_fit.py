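import math

import numpy as np
import pytest

from dpkf import _fast
from dpkf.fit import (
    crossval_predictive_ll,
    fit_participant,
    reconstruction_ll,
    response_nll,
    BOUNDS,
)
from dpkf.filter import run_filter
from dpkf.params import VARIANTS, Hyperparameters
from dpkf.task import DEFAULT_AGENT, build_session, simulate_responses


@pytest.fixture(scope="module")
def one_agent():
    rng = np.random.default_rng(77)
    sess = build_session("solo", rng)
    resp = simulate_responses(sess, DEFAULT_AGENT, rng)
    return sess, resp


def test_variant_free_parameter_counts():
    assert [VARIANTS[n].n_free for n in ("stationary_kf", "kf", "stationary_dpkf", "dpkf")] == [
        5, 7, 7, 9,
    ]


def test_fast_path_matches_reference_filter(one_agent):
    sess, _ = one_agent
    stims = np.stack([b.stimuli for b in sess.blocks])
    for hp in (
        DEFAULT_AGENT,
        DEFAULT_AGENT.replace(alpha=0.0, beta=0.0),
        DEFAULT_AGENT.replace(q=np.zeros(2)),
        DEFAULT_AGENT.replace(decay=0.9),
    ):
        for code, conv in ((_fast.PRED_MIXTURE, "mixture"), (_fast.PRED_MAP, "map")):
            preds, assigns, Ks = _fast.session_predictions(
                stims, hp.alpha, hp.beta, hp.q, hp.r, hp.decay, hp.m0, hp.c, code
            )
            for b in range(stims.shape[0]):
                tr = run_filter(stims[b], hp, prediction=conv)
                np.testing.assert_allclose(preds[b], tr.predicted_obs, atol=1e-10)
                np.testing.assert_array_equal(assigns[b], tr.assignments)
                assert Ks[b] == tr.n_modes


class TestResponseNll:
    def test_noise_free_responses_leave_only_the_constant_term(self, one_agent):
        sess, _ = one_agent
        rng = np.random.default_rng(0)
        hp = DEFAULT_AGENT.replace(v=np.array([2.0, 3.0]))
        noise_free = simulate_responses(sess, hp.replace(v=np.full(2, 1e-12)), rng)
        # score the noise-free responses under hp: residuals ~ 0
        nll = response_nll(noise_free, sess, hp)
        n = 12 * 18
        expected = sum(0.5 * n * math.log(2 * math.pi * v) for v in (2.0, 3.0))
        assert abs(nll - expected) < 1e-3

    def test_additive_over_blocks(self, one_agent):
        sess, resp = one_agent
        total = response_nll(resp, sess, DEFAULT_AGENT)
        parts = sum(response_nll(resp, sess, DEFAULT_AGENT, blocks=[i]) for i in range(12))
        assert abs(total - parts) < 1e-8

    def test_undersized_v_increases_nll(self, one_agent):
        sess, resp = one_agent
        good = response_nll(resp, sess, DEFAULT_AGENT)
        bad = response_nll(resp, sess, DEFAULT_AGENT.replace(v=DEFAULT_AGENT.v / 8))
        assert bad > good

    def test_empty_subset_rejected(self, one_agent):
        sess, resp = one_agent
        with pytest.raises(ValueError):
            response_nll(resp, sess, DEFAULT_AGENT, blocks=[])


class TestFitParticipant:
    def test_refit_with_same_seed_is_identical(self, one_agent):
        sess, resp = one_agent
        a = fit_participant(resp, sess, "kf", np.random.default_rng(9), compute_k=False)
        b = fit_participant(resp, sess, "kf", np.random.default_rng(9), compute_k=False)
        assert a.train_nll == b.train_nll
        np.testing.assert_array_equal(a.hyper.r, b.hyper.r)

    def test_bounds_respected_and_bookkeeping(self, one_agent):
        sess, resp = one_agent
        fr = fit_participant(resp, sess, "dpkf", np.random.default_rng(3))
        h = fr.hyper
        assert fr.train_nll == min(fr.restart_nlls)
        for val, key in (
            (h.v, "v"), (h.q, "q"), (h.r, "r"),
            (np.atleast_1d(h.alpha), "alpha"), (np.atleast_1d(h.beta), "beta"),
            (np.atleast_1d(h.decay), "decay"),
        ):
            lo, hi = BOUNDS[key]
            assert np.all(val >= lo - 1e-12) and np.all(val <= hi + 1e-12)
        assert set(fr.K_by_condition) == {"gradual", "jump"}

    def test_variant_restrictions_enforced(self, one_agent):
        sess, resp = one_agent
        rng = np.random.default_rng(4)
        st = fit_participant(resp, sess, "stationary_dpkf", rng, compute_k=False)
        assert np.all(st.hyper.q == 0)
        kf = fit_participant(resp, sess, "kf", rng, compute_k=False)
        assert kf.hyper.alpha == 0.0

    def test_nested_variants_never_beat_their_superset(self, one_agent):
        """Train NLL ordering dpkf <= kf <= stationary_kf and
        dpkf <= stationary_dpkf, up to optimizer tolerance."""
        sess, resp = one_agent
        rng = np.random.default_rng(5)
        tol = 1e-3
        st_kf = fit_participant(resp, sess, "stationary_kf", rng, compute_k=False)
        kf = fit_participant(resp, sess, "kf", rng, compute_k=False, extra_starts=(st_kf.hyper,))
        st_dp = fit_participant(
            resp, sess, "stationary_dpkf", rng, compute_k=False, extra_starts=(st_kf.hyper,)
        )
        dp = fit_participant(
            resp, sess, "dpkf", rng, compute_k=False, extra_starts=(kf.hyper, st_dp.hyper)
        )
        assert kf.train_nll <= st_kf.train_nll + tol
        assert st_dp.train_nll <= st_kf.train_nll + tol
        assert dp.train_nll <= kf.train_nll + tol
        assert dp.train_nll <= st_dp.train_nll + tol


def test_crossval_training_fit_bounds_heldout(agent_cohort):
    """Evaluating on the training blocks gives at least the held-out
    log-likelihood on average (overfitting direction check)."""
    sessions, resps = agent_cohort
    gaps = []
    for i, (sess, resp) in enumerate(zip(sessions, resps)):
        cv = crossval_predictive_ll(resp, sess, "kf", np.random.default_rng(100 + i))
        train_ll = -cv["fit_odd"]["train_nll"] - cv["fit_even"]["train_nll"]
        gaps.append(train_ll - cv["total_heldout_ll"])
    assert np.mean(gaps) > 0


def test_reconstruction_ll_flat_in_the_large_noise_limit(one_agent):
    sess, resp = one_agent
    huge_v = DEFAULT_AGENT.replace(v=np.full(2, 1e8))
    base = reconstruction_ll(resp, sess, huge_v)
    other = reconstruction_ll(resp, sess, huge_v.replace(alpha=0.0, beta=0.0))
    # with enormous response noise the model identity no longer matters
    assert abs(base - other) < 1e-3


def test_generating_model_scores_reconstructions_best(one_agent):
    """Noise-free reconstructions scored under the generating DP-KF beat
    the three restricted variants."""
    sess, _ = one_agent
    rng = np.random.default_rng(8)
    hp = DEFAULT_AGENT.replace(v=np.full(2, 1e-6))
    resp = simulate_responses(sess, hp, rng)
    score = DEFAULT_AGENT  # finite v for scoring
    lls = {}
    for name in VARIANTS:
        variant_hp = VARIANTS[name].restrict(score)
        lls[name] = reconstruction_ll(resp, sess, variant_hp)
    assert max(lls, key=lls.get) == "dpkf"
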
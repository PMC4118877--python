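"""ATAM sampler core: conditionals, joint likelihood, sweeps, audits."""

import math

import numpy as np
import pytest

from atam.model import (ATAMHypers, LatentState, SufficientStats,
                        ailment_conditional, gibbs_sweep, init_state,
                        joint_log_likelihood, token_conditional,
                        estimate_parameters)

from conftest import make_corpus, random_tiny_instance
from oracles import atam_log_joint


def _symmetric_hypers(A=2, Z=2, W=4, lam=0.5, **kw):
    defaults = dict(alpha=np.full((A, Z), 1.0), s=np.full(A, float(W)),
                    m=np.full((A, W), 1.0 / W), sigma=1.0, gamma_ail=1.0,
                    gamma_top=1.0, lam=lam, beta_flat=0.01)
    defaults.update(kw)
    return ATAMHypers(**defaults)


def _fresh(enc, hypers, seed=0):
    return init_state(enc, hypers, seed)


class TestInitState:
    def test_deterministic_for_fixed_seed(self):
        enc = make_corpus([[0, 1], [2]], [[0, 1], [2]], 4).encode()
        hypers = _symmetric_hypers()
        s1, _ = init_state(enc, hypers, 42)
        s2, _ = init_state(enc, hypers, 42)
        np.testing.assert_array_equal(s1.doc_ailment, s2.doc_ailment)
        np.testing.assert_array_equal(s1.token_state, s2.token_state)

    def test_empty_corpus_rejected(self):
        enc = make_corpus([], [], 0).encode()
        with pytest.raises(ValueError):
            init_state(enc, _symmetric_hypers(), 0)

    def test_audit_passes_on_random_corpora(self, rng):
        for _ in range(25):
            _, _, enc, hypers, _ = random_tiny_instance(rng)
            state, stats = init_state(enc, hypers, int(rng.integers(1 << 30)))
            stats.audit(enc, state, hypers.num_ailments, hypers.num_topics)


class TestAilmentConditional:
    def test_uniform_when_document_carries_no_evidence(self):
        # doc 0 all-background => AIL and TOP factors constant across i
        enc = make_corpus([[0, 1]], [[0, 0]], 4).encode()
        hypers = _symmetric_hypers()
        state = LatentState(np.array([0], np.int32),
                            np.zeros(2, np.int32), 1)  # both tokens BG
        stats = SufficientStats.from_state(enc, state, 2, 2)
        np.testing.assert_allclose(
            ailment_conditional(0, enc, state, stats, hypers), [0.5, 0.5])

    def test_single_ailment_token_predictive_arithmetic(self):
        # one AIL GENERAL token of word 0; beta_1=(1,1), beta_2=(3,1)
        # => p proportional to (1/2, 3/4) = (2/5, 3/5)
        enc = make_corpus([[0]], [[0]], 2).encode()
        hypers = _symmetric_hypers(
            A=2, Z=2, W=2,
            s=np.array([2.0, 4.0]), m=np.array([[0.5, 0.5], [0.75, 0.25]]))
        state = LatentState(np.array([0], np.int32),
                            np.array([1], np.int32), 1)  # AIL state
        stats = SufficientStats.from_state(enc, state, 2, 2)
        np.testing.assert_allclose(
            ailment_conditional(0, enc, state, stats, hypers), [0.4, 0.6],
            atol=1e-12)

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(8):
            dw, da, enc, hypers, kw = random_tiny_instance(rng)
            state, stats = init_state(enc, hypers, int(rng.integers(1 << 30)))
            nested, pos = [], 0
            for d in range(enc.num_docs):
                nested.append(list(state.token_state[pos:pos + len(dw[d])]))
                pos += len(dw[d])
            for d in range(enc.num_docs):
                probs = ailment_conditional(d, enc, state, stats, hypers)
                lp = []
                for cand in range(hypers.num_ailments):
                    a = list(state.doc_ailment)
                    a[d] = cand
                    lp.append(atam_log_joint(dw, da, a, nested, **kw))
                expected = np.exp(np.array(lp) - max(lp))
                expected /= expected.sum()
                np.testing.assert_allclose(probs, expected, atol=1e-10)

    def test_counts_restored_after_evaluation(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng)
        state, stats = init_state(enc, hypers, 3)
        before = stats.copy()
        ailment_conditional(0, enc, state, stats, hypers)
        assert stats.equals(before)


class TestTokenConditional:
    def test_symmetric_empty_stats(self):
        # empty counts, lam=0.5, gamma=1, Z=1 => (1/2, 1/4, 1/4)
        enc = make_corpus([[0]], [[0]], 4).encode()
        hypers = _symmetric_hypers(A=1, Z=1, lam=0.5)
        state = LatentState(np.array([0], np.int32), np.array([0], np.int32), 1)
        stats = SufficientStats.from_state(enc, state, 1, 1)
        np.testing.assert_allclose(
            token_conditional(0, 0, enc, state, stats, hypers),
            [0.5, 0.25, 0.25], atol=1e-12)

    def test_lam_zero_forces_background(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng)
        hypers.lam = 0.0
        state, stats = init_state(enc, hypers, 1)
        # make every token background so the state has positive probability
        state.token_state[:] = 0
        stats = SufficientStats.from_state(enc, state, hypers.num_ailments,
                                           hypers.num_topics)
        p = token_conditional(0, 0, enc, state, stats, hypers)
        assert p[0] == 1.0 and np.all(p[1:] == 0.0)

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(8):
            dw, da, enc, hypers, kw = random_tiny_instance(rng)
            state, stats = init_state(enc, hypers, int(rng.integers(1 << 30)))
            nested, pos = [], 0
            for d in range(enc.num_docs):
                nested.append(list(state.token_state[pos:pos + len(dw[d])]))
                pos += len(dw[d])
            for d in range(enc.num_docs):
                for n in range(len(dw[d])):
                    probs = token_conditional(d, n, enc, state, stats, hypers)
                    lp = []
                    for cand in range(hypers.num_topics + 2):
                        sn = [list(x) for x in nested]
                        sn[d][n] = cand
                        lp.append(atam_log_joint(dw, da,
                                                 list(state.doc_ailment),
                                                 sn, **kw))
                    expected = np.exp(np.array(lp) - max(lp))
                    expected /= expected.sum()
                    np.testing.assert_allclose(probs, expected, atol=1e-10)


class TestJointLogLikelihood:
    def test_empty_corpus_is_zero(self):
        enc = make_corpus([[0]], [[0]], 2).encode()
        hypers = _symmetric_hypers(W=2)
        state = LatentState(np.full(1, -1, np.int32),
                            np.full(1, -1, np.int32), 0)
        stats = SufficientStats.from_state(enc, state, 2, 2)
        assert joint_log_likelihood(enc, state, stats, hypers) == 0.0

    def test_single_background_token_closed_form(self):
        # log(1 - lam) + log(beta/(W beta)) + log(1/A)
        enc = make_corpus([[0]], [[0]], 2).encode()
        hypers = _symmetric_hypers(A=2, Z=2, W=2, lam=0.2)
        state = LatentState(np.array([0], np.int32), np.array([0], np.int32), 1)
        stats = SufficientStats.from_state(enc, state, 2, 2)
        expected = math.log(0.8) + math.log(0.01 / 0.02) + math.log(0.5)
        assert joint_log_likelihood(enc, state, stats, hypers) == \
            pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_on_random_configurations(self, rng):
        for _ in range(10):
            dw, da, enc, hypers, kw = random_tiny_instance(rng)
            state, stats = init_state(enc, hypers, int(rng.integers(1 << 30)))
            nested, pos = [], 0
            for d in range(enc.num_docs):
                nested.append(list(state.token_state[pos:pos + len(dw[d])]))
                pos += len(dw[d])
            expected = atam_log_joint(dw, da, list(state.doc_ailment),
                                      nested, **kw)
            assert joint_log_likelihood(enc, state, stats, hypers) == \
                pytest.approx(expected, abs=1e-9)


class TestGibbsSweep:
    def test_same_seed_same_trajectory(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng)
        runs = []
        for _ in range(2):
            state, stats = init_state(enc, hypers, 5)
            g = np.random.default_rng(17)
            for _ in range(20):
                gibbs_sweep(enc, state, stats, hypers, g)
            runs.append((state.doc_ailment.copy(), state.token_state.copy()))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_single_ailment_single_topic(self):
        enc = make_corpus([[0, 1], [2]], [[0, 1], [2]], 4).encode()
        hypers = _symmetric_hypers(A=1, Z=1)
        state, stats = init_state(enc, hypers, 0)
        gibbs_sweep(enc, state, stats, hypers, np.random.default_rng(0))
        assert np.all(state.doc_ailment == 0)
        assert np.all(np.isin(state.token_state, [0, 1, 2]))

    def test_counts_conserved_across_sweeps(self, rng):
        for _ in range(10):
            _, _, enc, hypers, _ = random_tiny_instance(rng, num_docs=4)
            state, stats = init_state(enc, hypers, int(rng.integers(1 << 30)))
            g = np.random.default_rng(int(rng.integers(1 << 30)))
            for _ in range(5):
                gibbs_sweep(enc, state, stats, hypers, g)
            stats.audit(enc, state, hypers.num_ailments, hypers.num_topics)


class TestEstimateParameters:
    def test_prior_means_recovered_without_data(self):
        enc = make_corpus([[0]], [[0]], 4).encode()
        hypers = _symmetric_hypers()
        state = LatentState(np.full(1, -1, np.int32),
                            np.full(1, -1, np.int32), 0)
        stats = SufficientStats.from_state(enc, state, 2, 2)
        est = estimate_parameters(enc, state, stats, hypers)
        np.testing.assert_allclose(est.eta, [0.5, 0.5])
        np.testing.assert_allclose(
            est.phi_ailment,
            np.broadcast_to(hypers.m[:, None, :], est.phi_ailment.shape))

    def test_eta_posterior_mean_arithmetic(self):
        # counts (3, 1) with sigma = 1 => (4/6, 2/6)
        enc = make_corpus([[0]] * 4, [[0]] * 4, 2).encode()
        hypers = _symmetric_hypers(W=2)
        state = LatentState(np.array([0, 0, 0, 1], np.int32),
                            np.zeros(4, np.int32), 4)
        stats = SufficientStats.from_state(enc, state, 2, 2)
        est = estimate_parameters(enc, state, stats, hypers)
        np.testing.assert_allclose(est.eta, [4 / 6, 2 / 6])

    def test_estimates_are_distributions(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng)
        state, stats = init_state(enc, hypers, 9)
        est = estimate_parameters(enc, state, stats, hypers)
        np.testing.assert_allclose(est.eta.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(est.theta.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(est.phi_topic.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(est.phi_ailment.sum(axis=2), 1.0, atol=1e-12)

    def test_phi_ailment_consistency_grows_with_data(self, rng):
        # posterior means of the ailment word distributions approach the
        # generating distributions as the corpus grows
        from atam.synthetic import TrueParams, generate_corpus
        params = TrueParams.well_separated(2, 2, 40, seed=3, lam=0.6)
        errs = []
        for n_docs in (60, 600):
            gen = generate_corpus(params, n_docs, 12, seed=4)
            enc = gen.corpus.encode()
            hypers = ATAMHypers(alpha=params.alpha, s=np.full(2, 40.0),
                                m=(params.phi_ailment * params.aspect_probs[:, :, None]).sum(1),
                                sigma=1.0, gamma_ail=1.0, gamma_top=1.0,
                                lam=params.lam, beta_flat=0.01)
            stats = SufficientStats.from_state(enc, gen.state, 2, 2)
            est = estimate_parameters(enc, gen.state, stats, hypers)
            errs.append(np.abs(est.phi_ailment - params.phi_ailment).sum(-1).mean())
        assert errs[1] < errs[0]
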
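"""Generative-story sampling, component matching, recovery scoring."""

import itertools

import numpy as np
import pytest

from atam.model import STATE_BG
from atam.synthetic import (GeneratedCorpus, TrueParams, generate_corpus,
                            match_components, recovery_report)


def _params(A=2, Z=2, W=30, **kw):
    return TrueParams.well_separated(A, Z, W, seed=1, **kw)


class TestGenerateCorpus:
    def test_lam_zero_yields_only_background(self):
        params = _params(lam=0.0)
        gen = generate_corpus(params, 30, 6, seed=2)
        assert np.all(gen.state.token_state == STATE_BG)
        # and every word must then carry background-distribution support
        for doc in gen.corpus.documents:
            for tok in doc.tokens:
                assert params.phi_background[int(tok.aspect), tok.word_id] > 0

    def test_one_hot_eta_pins_every_ailment(self):
        params = _params()
        params.eta = np.array([1.0, 0.0])
        gen = generate_corpus(params, 40, 5, seed=3)
        assert np.all(gen.state.doc_ailment == 0)

    def test_deterministic_given_seed(self):
        params = _params()
        a = generate_corpus(params, 20, 5, seed=9)
        b = generate_corpus(params, 20, 5, seed=9)
        np.testing.assert_array_equal(a.state.doc_ailment, b.state.doc_ailment)
        assert [[t.word_id for t in d.tokens] for d in a.corpus.documents] == \
               [[t.word_id for t in d.tokens] for d in b.corpus.documents]

    def test_word_marginals_match_implied_mixture(self):
        """Empirical word frequencies over a large sample agree with the
        mixture implied by the generating parameters within 3 SE per word."""
        params = _params(A=2, Z=2, W=25, lam=0.4)
        params.eta = np.array([0.6, 0.4])
        n_docs, n_len = 10_000, 10
        gen = generate_corpus(params, n_docs, n_len, seed=4)
        counts = np.zeros(25)
        for doc in gen.corpus.documents:
            for tok in doc.tokens:
                counts[tok.word_id] += 1
        total = counts.sum()

        # implied marginal: mixture over ailment, aspect, bg/ail/topic routes
        # (pi_d ~ Beta(1,1) has mean 1/2; theta_d ~ Dir(alpha_i) has mean
        # alpha_i / sum(alpha_i))
        marginal = np.zeros(25)
        for i in range(2):
            theta_mean = params.alpha[i] / params.alpha[i].sum()
            topic_mix = theta_mean @ params.phi_topic
            for j in range(3):
                w = params.eta[i] * params.aspect_probs[i, j]
                marginal += w * ((1 - params.lam) * params.phi_background[j]
                                 + params.lam * (0.5 * params.phi_ailment[i, j]
                                                 + 0.5 * topic_mix))
        se = np.sqrt(marginal * (1 - marginal) / total)
        # per-document correlations inflate the variance slightly; 3 SE on
        # the binomial scale plus a small absolute floor
        assert np.all(np.abs(counts / total - marginal) < 3 * se + 0.003)

    def test_planted_temporal_intensity_shapes_bin_rates(self):
        intensity = np.ones((2, 6))
        intensity[0] = [2.0, 2.0, 2.0, 0.25, 0.25, 0.25]
        params = _params(temporal_intensity=intensity)
        gen = generate_corpus(params, 3000, 4, seed=5)
        early = gen.state.doc_ailment[gen.bin_of_doc < 3].mean()
        late = gen.state.doc_ailment[gen.bin_of_doc >= 3].mean()
        # ailment 0 dominates early bins => mean label smaller there
        assert early < late
        assert gen.corpus.documents[0].timestamp is not None

    def test_dimension_mismatch_rejected(self):
        params = _params()
        with pytest.raises(ValueError):
            TrueParams(eta=params.eta, alpha=params.alpha,
                       phi_ailment=params.phi_ailment[:, :, :10],
                       phi_topic=params.phi_topic,
                       phi_background=params.phi_background)


class TestMatchComponents:
    def test_shuffled_identical_sets_recovered_exactly(self, rng):
        true = rng.dirichlet(np.full(8, 0.5), size=5)
        perm_true = rng.permutation(5)
        est = true[perm_true]
        perm, cost = match_components(true, est)
        assert cost == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(true, est[perm])

    def test_two_by_two_distance_matrix(self):
        # L1 distances [[0.1, 0.9], [0.9, 0.1]] => identity, cost 0.2
        true = np.array([[0.5, 0.5], [0.1, 0.9]])
        est = np.array([[0.55, 0.45], [0.15, 0.85]])
        perm, cost = match_components(true, est)
        np.testing.assert_array_equal(perm, [0, 1])
        assert cost == pytest.approx(0.2, abs=1e-12)

    def test_matches_exhaustive_search(self, rng):
        for n in (2, 4, 6):
            true = rng.dirichlet(np.full(5, 1.0), size=n)
            est = rng.dirichlet(np.full(5, 1.0), size=n)
            _, cost = match_components(true, est)
            brute = min(
                sum(np.abs(true[i] - est[p[i]]).sum() for i in range(n))
                for p in itertools.permutations(range(n)))
            assert cost == pytest.approx(brute, abs=1e-10)

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError):
            match_components(np.eye(3), np.eye(4)[:3, :].T.reshape(4, 3))


class TestRecoveryReport:
    def _perfect_estimates(self, params, gen):
        from atam.model import ParameterEstimates
        D, Z = gen.state.doc_ailment.size, params.num_topics
        return ParameterEstimates(
            eta=params.eta.copy(), pi=np.full(D, 0.5),
            theta=np.full((D, Z), 1.0 / Z),
            phi_topic=params.phi_topic.copy(),
            phi_ailment=params.phi_ailment.copy(),
            phi_background=params.phi_background.copy())

    def test_perfect_estimates_score_perfectly(self):
        params = _params()
        gen = generate_corpus(params, 50, 5, seed=6)
        rep = recovery_report(gen, params, self._perfect_estimates(params, gen),
                              gen.state.doc_ailment)
        assert rep["doc_ailment_accuracy"] == 1.0
        assert rep["phi_ailment_mean_l1"] == pytest.approx(0.0, abs=1e-12)
        assert rep["eta_max_abs_error"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_rows_vs_one_hot_truth_closed_form(self):
        # L1(uniform over W, one-hot) = 2 (W - 1) / W per row
        W = 30
        params = _params(W=W)
        one_hot = np.zeros((2, 3, W))  # every ailment/aspect row one-hot on w0
        one_hot[..., 0] = 1.0
        params_oh = TrueParams(eta=params.eta, alpha=params.alpha,
                               phi_ailment=one_hot,
                               phi_topic=params.phi_topic,
                               phi_background=params.phi_background,
                               lam=params.lam)
        gen = generate_corpus(params_oh, 20, 4, seed=7)
        est = self._perfect_estimates(params_oh, gen)
        est.phi_ailment = np.full((2, 3, W), 1.0 / W)
        rep = recovery_report(gen, params_oh, est, gen.state.doc_ailment)
        assert rep["phi_ailment_mean_l1"] == pytest.approx(2 * (W - 1) / W)


def test_inference_beats_chance_on_well_separated_data():
    """generate -> infer with the generating priors -> accuracy above 1/A."""
    from atam.model import ATAMHypers, gibbs_sweep, init_state, estimate_parameters

    params = _params(A=2, Z=2, W=40, lam=0.6)
    gen = generate_corpus(params, 150, 10, seed=8)
    enc = gen.corpus.encode()
    m = (params.aspect_probs[:, :, None] * params.phi_ailment).sum(axis=1)
    hypers = ATAMHypers(alpha=params.alpha.copy(), s=np.full(2, 100.0), m=m,
                        sigma=1.0, gamma_ail=1.0, gamma_top=1.0,
                        lam=params.lam, beta_flat=0.01)
    state, stats = init_state(enc, hypers, 9)
    g = np.random.default_rng(10)
    for _ in range(150):
        gibbs_sweep(enc, state, stats, hypers, g)
    est = estimate_parameters(enc, state, stats, hypers)
    rep = recovery_report(gen, params, est, state.doc_ailment)
    assert rep["doc_ailment_accuracy"] > 0.5
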
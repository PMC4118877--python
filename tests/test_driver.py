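"""Training orchestration: schedule, incremental data, pooling, resume."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atam.driver import (extend_data, load_checkpoint, make_schedule,
                         pooled_sweep, save_checkpoint, train)
from atam.model import SufficientStats, gibbs_sweep, init_state, joint_log_likelihood
from atam.priors import ModelConfig
from atam.synthetic import TrueParams, generate_corpus

from conftest import random_tiny_instance


class TestMakeSchedule:
    def test_degenerate_one_sweep_per_level(self):
        sched = make_schedule(10, 10)
        assert sched.sweeps == [1] * 10
        assert sched.fractions[-1] == 1.0

    def test_more_sweeps_on_less_data(self):
        sched = make_schedule(8000, 10)
        assert sched.sweeps == sorted(sched.sweeps, reverse=True)
        assert sum(sched.sweeps) == 8000
        assert sched.sweeps[0] > sched.sweeps[-1]

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=10, max_value=100000))
    def test_sum_and_monotonicity_for_random_totals(self, total):
        sched = make_schedule(total, 10)
        assert sum(sched.sweeps) == total
        assert all(a >= b for a, b in zip(sched.sweeps, sched.sweeps[1:]))
        assert all(s >= 1 for s in sched.sweeps)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(5, 10)
        with pytest.raises(ValueError):
            make_schedule(10, 0)


class TestExtendData:
    def test_zero_new_documents_is_noop(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng, num_docs=4)
        state, stats = init_state(enc, hypers, 1, num_active=4)
        before = stats.copy()
        extend_data(enc, state, stats, hypers, 4)
        assert stats.equals(before)

    def test_extension_passes_audit_on_random_corpora(self, rng):
        for _ in range(15):
            _, _, enc, hypers, _ = random_tiny_instance(rng, num_docs=6)
            state, stats = init_state(enc, hypers, int(rng.integers(1 << 30)),
                                      num_active=2)
            g = np.random.default_rng(int(rng.integers(1 << 30)))
            gibbs_sweep(enc, state, stats, hypers, g)
            extend_data(enc, state, stats, hypers, 6)
            assert state.num_active == 6
            stats.audit(enc, state, hypers.num_ailments, hypers.num_topics)

    def test_greedy_assignment_takes_argmax_of_two_way_choice(self, rng):
        # A=1, Z=1: each new token goes to the single most probable of
        # BG / AIL / TOP(0) under the current conditional
        from atam.model import ATAMHypers, token_conditional
        from conftest import make_corpus
        enc = make_corpus([[0], [0]], [[0], [0]], 2).encode()
        hypers = ATAMHypers(alpha=np.array([[1.0]]), s=np.array([2.0]),
                            m=np.array([[0.5, 0.5]]), sigma=1.0,
                            gamma_ail=1.0, gamma_top=1.0, lam=0.2,
                            beta_flat=0.01)
        state, stats = init_state(enc, hypers, 0, num_active=1)
        extend_data(enc, state, stats, hypers, 2)
        p = token_conditional(1, 0, enc, state, stats, hypers)
        assert state.token_state[1] == int(np.argmax(p))

    def test_cannot_shrink(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng, num_docs=3)
        state, stats = init_state(enc, hypers, 1, num_active=3)
        with pytest.raises(ValueError):
            extend_data(enc, state, stats, hypers, 2)


class TestPooledSweep:
    def test_single_shard_bit_identical_to_plain_sweep(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng, num_docs=5)
        s1, st1 = init_state(enc, hypers, 4)
        s2, st2 = init_state(enc, hypers, 4)
        gibbs_sweep(enc, s1, st1, hypers, np.random.default_rng(99))
        pooled_sweep(enc, s2, st2, hypers, [np.arange(5)], 99)
        np.testing.assert_array_equal(s1.doc_ailment, s2.doc_ailment)
        np.testing.assert_array_equal(s1.token_state, s2.token_state)
        assert st1.equals(st2)

    def test_pooled_counts_equal_recount(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng, num_docs=8)
        state, stats = init_state(enc, hypers, 4)
        shards = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 8)]
        pooled_sweep(enc, state, stats, hypers, shards, 7)
        fresh = SufficientStats.from_state(enc, state, hypers.num_ailments,
                                           hypers.num_topics)
        assert stats.equals(fresh)

    def test_empty_shard_allowed(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng, num_docs=4)
        state, stats = init_state(enc, hypers, 4)
        pooled_sweep(enc, state, stats, hypers,
                     [np.arange(4), np.empty(0, np.int64)], 7)
        stats.audit(enc, state, hypers.num_ailments, hypers.num_topics)

    def test_overlapping_shards_rejected(self, rng):
        _, _, enc, hypers, _ = random_tiny_instance(rng, num_docs=4)
        state, stats = init_state(enc, hypers, 4)
        with pytest.raises(ValueError, match="overlap"):
            pooled_sweep(enc, state, stats, hypers,
                         [np.array([0, 1]), np.array([1, 2, 3])], 7)


def _small_setup(seed=0):
    params = TrueParams.well_separated(2, 2, 40, seed=seed, lam=0.5)
    gen = generate_corpus(params, 60, 8, seed=seed + 1)
    config = ModelConfig(num_ailments=2, num_topics=2, iterations=40,
                         num_increments=4, lam=0.5,
                         log_likelihood_every=10, seed=seed)
    return gen.corpus.encode(), config


class TestTrain:
    def test_default_iterations_is_study_setting(self):
        assert ModelConfig().iterations == 8000

    def test_likelihood_improves_over_initialization(self):
        enc, config = _small_setup()
        config = ModelConfig(**{**config.to_dict(), "num_increments": 1,
                                "optimize_hypers": False})
        ckpt = train(enc, config, seed=1)
        state0, stats0 = init_state(enc, ckpt.hypers, 123)
        ll_init = joint_log_likelihood(enc, state0, stats0, ckpt.hypers)
        ll_final = joint_log_likelihood(enc, ckpt.state, ckpt.stats,
                                        ckpt.hypers)
        assert ckpt.state.num_active == enc.num_docs
        assert ll_final > ll_init

    def test_resume_reproduces_uninterrupted_run(self, tmp_path):
        enc, config = _small_setup(seed=5)
        full = train(enc, config, seed=5)

        half = train(enc, config, seed=5, stop_at=20)
        p = tmp_path / "ckpt.npz"
        save_checkpoint(half, p)
        resumed = train(enc, config, seed=5, checkpoint=load_checkpoint(p))

        np.testing.assert_array_equal(full.state.doc_ailment,
                                      resumed.state.doc_ailment)
        np.testing.assert_array_equal(full.state.token_state,
                                      resumed.state.token_state)
        np.testing.assert_array_equal(full.hypers.alpha, resumed.hypers.alpha)
        np.testing.assert_array_equal(full.hypers.s, resumed.hypers.s)
        assert full.stats.equals(resumed.stats)

    def test_determinism_of_full_run(self):
        enc, config = _small_setup(seed=9)
        a = train(enc, config, seed=9)
        b = train(enc, config, seed=9)
        np.testing.assert_array_equal(a.state.token_state, b.state.token_state)
        np.testing.assert_array_equal(a.hypers.alpha, b.hypers.alpha)

    def test_final_state_passes_audit(self):
        enc, config = _small_setup(seed=3)
        ckpt = train(enc, config, seed=3)
        ckpt.stats.audit(enc, ckpt.state, config.num_ailments,
                         config.num_topics)
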
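"""Reference validation experiments.

Self-contained, seeded experiments that exercise the whole stack on
synthetic data with known ground truth: long-run agreement of the Gibbs
samplers with brute-force enumerated posteriors, conditional-versus-
enumeration agreement, parameter recovery on a well-separated corpus,
Minka-update recovery of known hyperparameters, and recovery of a
planted temporal trend.  Problem sizes are chosen so the full battery
runs in minutes on one core; the same functions back the test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .corpus import Aspect, Corpus, Document, Token, Vocabulary
from .exact import (atam_config_id, enumerate_atam_posterior,
                    enumerate_lda_posterior, lda_config_id)
from .hyperopt import (HyperoptSchedule, dirmult_log_likelihood,
                       fixed_mean_log_likelihood, optimize_atam_hypers,
                       update_alpha, update_precision)
from .lda_bg import (LDABGHypers, lda_gibbs_sweep, lda_init_state,
                     lda_token_conditional)
from .model import (ATAMHypers, ailment_conditional, estimate_parameters,
                    gibbs_sweep, init_state, joint_log_likelihood,
                    token_conditional, LatentState, SufficientStats)
from .priors import build_prior_means
from .synthetic import TrueParams, generate_corpus, recovery_report
from .trends import ailment_rate, pearson

__all__ = [
    "sampler_posterior_agreement",
    "conditional_enumeration_agreement",
    "parameter_recovery",
    "hyperparameter_recovery",
    "trend_recovery",
]


def _tiny_corpus(doc_words, doc_aspects, num_words) -> Corpus:
    vocab = Vocabulary(f"w{v}" for v in range(num_words))
    docs = []
    for d, (ws, ys) in enumerate(zip(doc_words, doc_aspects)):
        docs.append(Document(doc_id=f"d{d}", tokens=[
            Token(word_id=w, aspect=Aspect(y), surface=vocab.word(w))
            for w, y in zip(ws, ys)]))
    return Corpus(documents=docs, vocab=vocab)


def sampler_posterior_agreement(seed: int, n_sweeps: int = 200_000,
                                burn_in: int = 2_000) -> dict:
    """Total-variation distance between long-run Gibbs frequencies and the
    enumerated exact posterior, for ATAM and the LDA baseline.

    The instance is tiny (A = Z = 2, W = 4, three short documents with
    fixed aspects) with informative word-prior means so the posterior is
    concentrated enough for the empirical frequencies to be estimable.
    """
    enc = _tiny_corpus([[0], [1], [2]], [[1], [0], [2]], 4).encode()
    hypers = ATAMHypers(alpha=np.array([[1.5, 0.5], [0.5, 1.5]]),
                        s=np.array([8.0, 8.0]),
                        m=np.array([[0.7, 0.1, 0.1, 0.1],
                                    [0.1, 0.7, 0.1, 0.1]]),
                        sigma=1.0, gamma_ail=1.0, gamma_top=1.0,
                        lam=0.5, beta_flat=0.25)
    exact = enumerate_atam_posterior(enc, hypers)
    state, stats = init_state(enc, hypers, seed)
    rng = np.random.default_rng(seed)
    for _ in range(burn_in):
        gibbs_sweep(enc, state, stats, hypers, rng)
    counts = np.zeros(exact.size)
    num_states = hypers.num_topics + 2
    for _ in range(n_sweeps):
        gibbs_sweep(enc, state, stats, hypers, rng)
        counts[atam_config_id(state.doc_ailment, state.token_state,
                              hypers.num_ailments, num_states)] += 1
    tv_atam = 0.5 * np.abs(counts / counts.sum() - exact).sum()
    stats.audit(enc, state, hypers.num_ailments, hypers.num_topics)

    enc_l = _tiny_corpus([[0, 0], [1], [2]], [[0, 0], [0], [0]], 4).encode()
    lh = LDABGHypers(alpha=np.array([1.5, 0.5]), lam=0.5, beta_flat=0.1)
    exact_l = enumerate_lda_posterior(enc_l, lh)
    lstate, lstats = lda_init_state(enc_l, lh, seed)
    lrng = np.random.default_rng(seed + 1)
    for _ in range(burn_in):
        lda_gibbs_sweep(enc_l, lstate, lstats, lh, lrng)
    counts_l = np.zeros(exact_l.size)
    for _ in range(n_sweeps):
        lda_gibbs_sweep(enc_l, lstate, lstats, lh, lrng)
        counts_l[lda_config_id(lstate.token_state, lh.num_topics + 1)] += 1
    tv_lda = 0.5 * np.abs(counts_l / counts_l.sum() - exact_l).sum()
    return {"tv_atam": float(tv_atam), "tv_lda": float(tv_lda),
            "n_sweeps": n_sweeps,
            "n_configs_atam": int(exact.size),
            "n_configs_lda": int(exact_l.size)}


def _random_tiny_instance(rng):
    A = Z = 2
    W = 4
    doc_words = [list(rng.integers(0, W, size=rng.integers(1, 5)))
                 for _ in range(3)]
    doc_aspects = [list(rng.integers(0, 3, size=len(w))) for w in doc_words]
    enc = _tiny_corpus(doc_words, doc_aspects, W).encode()
    hypers = ATAMHypers(alpha=rng.uniform(0.2, 2.0, size=(A, Z)),
                        s=rng.uniform(0.5, 8.0, size=A),
                        m=rng.dirichlet(np.full(W, 0.8), size=A),
                        sigma=float(rng.uniform(0.3, 2.0)),
                        gamma_ail=float(rng.uniform(0.3, 2.0)),
                        gamma_top=float(rng.uniform(0.3, 2.0)),
                        lam=float(rng.uniform(0.1, 0.9)),
                        beta_flat=float(rng.uniform(0.05, 1.0)))
    return enc, hypers


def conditional_enumeration_agreement(seed: int,
                                      n_instances: int = 50) -> dict:
    """Max entrywise deviation of the three collapsed conditionals from
    renormalized exact joint probabilities on random tiny instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        enc, hypers = _random_tiny_instance(rng)
        A, Z = hypers.num_ailments, hypers.num_topics
        state, stats = init_state(enc, hypers, int(rng.integers(1 << 31)))

        def joint_of(st):
            s = SufficientStats.from_state(enc, st, A, Z)
            return joint_log_likelihood(enc, st, s, hypers)

        for d in range(enc.num_docs):
            probs = ailment_conditional(d, enc, state, stats, hypers)
            lp = []
            for cand in range(A):
                alt = state.copy()
                alt.doc_ailment[d] = cand
                lp.append(joint_of(alt))
            expected = np.exp(np.array(lp) - max(lp))
            worst = max(worst, float(np.max(np.abs(
                probs - expected / expected.sum()))))
            for n in range(int(enc.doc_ptr[d + 1] - enc.doc_ptr[d])):
                probs = token_conditional(d, n, enc, state, stats, hypers)
                lp = []
                for cand in range(Z + 2):
                    alt = state.copy()
                    alt.token_state[int(enc.doc_ptr[d]) + n] = cand
                    lp.append(joint_of(alt))
                expected = np.exp(np.array(lp) - max(lp))
                worst = max(worst, float(np.max(np.abs(
                    probs - expected / expected.sum()))))

        # LDA baseline on the same corpus shape, GENERAL aspects
        lh = LDABGHypers(alpha=rng.uniform(0.2, 2.0, size=2),
                         lam=float(rng.uniform(0.1, 0.9)),
                         beta_flat=float(rng.uniform(0.05, 1.0)))
        from .lda_bg import LDABGStats, lda_joint_log_likelihood
        lstate, lstats = lda_init_state(enc, lh, int(rng.integers(1 << 31)))
        for d in range(enc.num_docs):
            for n in range(int(enc.doc_ptr[d + 1] - enc.doc_ptr[d])):
                probs = lda_token_conditional(d, n, enc, lstate, lstats, lh)
                lp = []
                for cand in range(lh.num_topics + 1):
                    alt = lstate.copy()
                    alt.token_state[int(enc.doc_ptr[d]) + n] = cand
                    s = LDABGStats.from_state(enc, alt, lh.num_topics)
                    lp.append(lda_joint_log_likelihood(enc, alt, s, lh))
                expected = np.exp(np.array(lp) - max(lp))
                worst = max(worst, float(np.max(np.abs(
                    probs - expected / expected.sum()))))
    return {"max_abs_deviation": worst, "n_instances": n_instances}


def _reference_prior_set(params: TrueParams, vocab, rng,
                         tokens_per_ailment: int = 3000,
                         s_init: float = 200.0):
    """Synthetic per-ailment reference texts drawn from the true ailment
    word distributions (aspect-mixed), then the standard prior builder."""
    texts = []
    for i in range(params.num_ailments):
        mix = (params.aspect_probs[i][:, None] * params.phi_ailment[i]).sum(0)
        toks = rng.choice(params.num_words, p=mix, size=tokens_per_ailment)
        texts.append([" ".join(vocab.word(int(v)) for v in toks)])
    return build_prior_means(texts, vocab, smoothing=0.01, s_init=s_init)


def parameter_recovery(seed: int, num_docs: int = 2000, doc_len: int = 15,
                       n_sweeps: int = 2000) -> dict:
    """Standard recovery run: A = Z = 3, W = 200, well-separated word
    distributions, informative priors at precision 200, interleaved
    hyperparameter optimization."""
    params = TrueParams.well_separated(3, 3, 200, seed=seed, lam=0.5)
    gen = generate_corpus(params, num_docs, doc_len, seed=seed + 1)
    enc = gen.corpus.encode()
    rng = np.random.default_rng(seed + 2)
    prior_set = _reference_prior_set(params, gen.corpus.vocab, rng)
    hypers = ATAMHypers(alpha=np.full((3, 3), 1.0), s=prior_set.precisions,
                        m=prior_set.means, sigma=1.0, gamma_ail=1.0,
                        gamma_top=1.0, lam=params.lam, beta_flat=0.01)
    state, stats = init_state(enc, hypers, seed + 3)
    sweep_rng = np.random.default_rng(seed + 4)
    sched = HyperoptSchedule(interval=10, passes=2)
    for sweep in range(n_sweeps):
        gibbs_sweep(enc, state, stats, hypers, sweep_rng)
        if sched.due(sweep):
            optimize_atam_hypers(state, stats, hypers, sched)
    est = estimate_parameters(enc, state, stats, hypers)
    rep = recovery_report(gen, params, est, state.doc_ailment)
    rep["n_docs"] = num_docs
    return rep


def hyperparameter_recovery(seed: int, n_groups: int = 10_000,
                            tokens_per_group: int = 100) -> dict:
    """Minka updates versus grid search on simulated counts.

    Precision: counts from Dirichlet(s_true * m)-multinomial groups; the
    fixed point must sit within 10% of the 1-D grid maximizer.  Alpha:
    2-dimensional counts from a known alpha; the fixed point must agree
    with a dense 2-D grid search within grid resolution.  Also verifies
    that an interleaved optimization event never decreases the collapsed
    joint likelihood on a fixed latent state.
    """
    rng = np.random.default_rng(seed)
    W = 20
    m = rng.dirichlet(np.full(W, 2.0))
    s_true = 50.0
    ps = rng.dirichlet(s_true * m, size=n_groups)
    counts = np.vstack([rng.multinomial(tokens_per_group, p) for p in ps])
    s = 1.0
    for _ in range(500):
        s_new = update_precision(counts, m, s)
        if abs(s_new - s) < 1e-10:
            break
        s = s_new
    grid = np.linspace(0.5 * s, 1.5 * s, 201)
    lls = [fixed_mean_log_likelihood(counts, m, g) for g in grid]
    s_grid = float(grid[int(np.argmax(lls))])

    alpha_true = np.array([2.0, 0.7])
    th = rng.dirichlet(alpha_true, size=4000)
    counts2 = np.vstack([rng.multinomial(30, p) for p in th])
    alpha = np.array([1.0, 1.0])
    for _ in range(2000):
        alpha_new = update_alpha(counts2, alpha)
        if np.max(np.abs(alpha_new - alpha)) < 1e-12:
            break
        alpha = alpha_new
    step = 0.02
    g1 = np.arange(max(step, alpha[0] - 0.5), alpha[0] + 0.5, step)
    g2 = np.arange(max(step, alpha[1] - 0.5), alpha[1] + 0.5, step)
    best = max(((dirmult_log_likelihood(counts2, np.array([a, b])), a, b)
                for a in g1 for b in g2))
    alpha_grid = np.array(best[1:])

    # optimization event monotonicity on a small sampled state
    params = TrueParams.well_separated(2, 2, 40, seed=seed + 5, lam=0.5)
    gen = generate_corpus(params, 100, 8, seed=seed + 6)
    enc = gen.corpus.encode()
    hypers = ATAMHypers(alpha=np.full((2, 2), 1.0), s=np.full(2, 50.0),
                        m=(params.aspect_probs[:, :, None]
                           * params.phi_ailment).sum(1),
                        sigma=1.0, gamma_ail=1.0, gamma_top=1.0,
                        lam=0.5, beta_flat=0.01)
    state, stats = init_state(enc, hypers, seed + 7)
    g = np.random.default_rng(seed + 8)
    min_delta = np.inf
    sched = HyperoptSchedule(passes=3, min_group=1)
    for _ in range(5):
        for _ in range(10):
            gibbs_sweep(enc, state, stats, hypers, g)
        before = joint_log_likelihood(enc, state, stats, hypers)
        optimize_atam_hypers(state, stats, hypers, sched)
        after = joint_log_likelihood(enc, state, stats, hypers)
        min_delta = min(min_delta, after - before)

    return {
        "s_true": s_true,
        "s_fixed_point": float(s),
        "s_grid": s_grid,
        "s_rel_err_vs_grid": abs(s - s_grid) / s_grid,
        "s_rel_err_vs_true": abs(s - s_true) / s_true,
        "alpha_fixed_point": alpha.tolist(),
        "alpha_grid": alpha_grid.tolist(),
        "alpha_max_dev_vs_grid": float(np.max(np.abs(alpha - alpha_grid))),
        "alpha_grid_step": step,
        "min_likelihood_delta_per_event": float(min_delta),
        "n_groups": n_groups,
    }


def trend_recovery(seed: int, docs_per_bin: int = 5000, n_bins: int = 20,
                   doc_len: int = 10, n_sweeps: int = 100) -> dict:
    """Recover a planted sinusoidal ailment intensity from weekly rates.

    Ailment 0's prevalence oscillates across the bins; after training,
    the Pearson correlation between the inferred weekly rate series for
    the matched ailment and the planted per-bin assignment probability
    is reported.
    """
    intensity = np.ones((3, n_bins))
    intensity[0] = 1.0 + 0.8 * np.sin(2 * np.pi * np.arange(n_bins) / n_bins)
    params = TrueParams.well_separated(3, 2, 150, seed=seed, lam=0.5,
                                       temporal_intensity=intensity)
    gen = generate_corpus(params, docs_per_bin * n_bins, doc_len,
                          seed=seed + 1)
    enc = gen.corpus.encode()
    rng = np.random.default_rng(seed + 2)
    prior_set = _reference_prior_set(params, gen.corpus.vocab, rng)
    hypers = ATAMHypers(alpha=np.full((3, 2), 1.0), s=prior_set.precisions,
                        m=prior_set.means, sigma=1.0, gamma_ail=1.0,
                        gamma_top=1.0, lam=params.lam, beta_flat=0.01)
    state, stats = init_state(enc, hypers, seed + 3)
    sweep_rng = np.random.default_rng(seed + 4)
    for _ in range(n_sweeps):
        gibbs_sweep(enc, state, stats, hypers, sweep_rng)
    # informative priors anchor component identity, but match anyway
    est = estimate_parameters(enc, state, stats, hypers)
    from .synthetic import match_components
    perm, _ = match_components(params.phi_ailment, est.phi_ailment)
    series = ailment_rate(state.doc_ailment, gen.corpus, "week",
                          int(perm[0]))
    planted = gen.bin_ailment_probs[:, 0]
    r = pearson(series.rates, planted)
    accuracy = float(np.mean(state.doc_ailment
                             == perm[gen.state.doc_ailment]))
    return {"pearson_r": float(r), "doc_accuracy": accuracy,
            "n_docs": docs_per_bin * n_bins, "n_bins": len(series.bins)}
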
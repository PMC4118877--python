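"""LDA with a shared background word distribution (baseline model).

Each token is either drawn from the corpus-wide background distribution
(probability 1 - lam) or generated by standard LDA (probability lam).
Collapsed Gibbs over token states {BG} + {TOP(k)}; token state codes:
0 background, 1 + k topic k.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln

from . import _kernels as K
from .corpus import EncodedCorpus

__all__ = [
    "LDABGHypers",
    "LDABGState",
    "LDABGStats",
    "lda_init_state",
    "lda_token_conditional",
    "lda_gibbs_sweep",
    "lda_joint_log_likelihood",
    "lda_estimate_parameters",
]

UNASSIGNED = -1


@dataclasses.dataclass
class LDABGHypers:
    alpha: np.ndarray  # (Z,) Dirichlet over document topic distributions
    lam: float = 0.2   # probability a token is non-background
    beta_flat: float = 0.01

    def __post_init__(self) -> None:
        self.alpha = np.ascontiguousarray(self.alpha, dtype=np.float64)

    @property
    def num_topics(self) -> int:
        return self.alpha.shape[0]

    @classmethod
    def symmetric(cls, num_topics: int, alpha: float = 1.0,
                  lam: float = 0.2, beta_flat: float = 0.01) -> "LDABGHypers":
        return cls(alpha=np.full(num_topics, alpha), lam=lam,
                   beta_flat=beta_flat)


@dataclasses.dataclass
class LDABGState:
    token_state: np.ndarray  # int32 (T,)
    num_active: int

    def copy(self) -> "LDABGState":
        return LDABGState(self.token_state.copy(), self.num_active)


@dataclasses.dataclass
class LDABGStats:
    n_doc_topic: np.ndarray  # (D, Z)
    n_topic_word: np.ndarray  # (Z, W)
    n_topic_sum: np.ndarray   # (Z,)
    n_bg_word: np.ndarray    # (W,)
    n_bg_sum: np.ndarray     # (1,) kept as an array for in-place kernels
    n_doc_top: np.ndarray    # (D,)

    @classmethod
    def from_state(cls, corpus: EncodedCorpus, state: LDABGState,
                   num_topics: int) -> "LDABGStats":
        D, W = corpus.num_docs, corpus.num_words
        stats = cls(
            n_doc_topic=np.zeros((D, num_topics), np.int64),
            n_topic_word=np.zeros((num_topics, W), np.int64),
            n_topic_sum=np.zeros(num_topics, np.int64),
            n_bg_word=np.zeros(W, np.int64),
            n_bg_sum=np.zeros(1, np.int64),
            n_doc_top=np.zeros(D, np.int64),
        )
        ts = state.token_state
        token_doc = corpus.token_doc()
        bg = ts == 0
        np.add.at(stats.n_bg_word, corpus.words[bg], 1)
        stats.n_bg_sum[0] = int(bg.sum())
        top = ts >= 1
        ks = ts[top] - 1
        np.add.at(stats.n_topic_word, (ks, corpus.words[top]), 1)
        stats.n_topic_sum[:] = stats.n_topic_word.sum(axis=1)
        np.add.at(stats.n_doc_topic, (token_doc[top], ks), 1)
        np.add.at(stats.n_doc_top, token_doc[top], 1)
        return stats

    def copy(self) -> "LDABGStats":
        return LDABGStats(**{f.name: getattr(self, f.name).copy()
                             for f in dataclasses.fields(self)})

    def audit(self, corpus: EncodedCorpus, state: LDABGState,
              num_topics: int) -> None:
        fresh = LDABGStats.from_state(corpus, state, num_topics)
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(fresh, f.name)
            if not np.array_equal(a, b):
                raise AssertionError(f"LDA statistic {f.name} inconsistent")


def lda_init_state(corpus: EncodedCorpus, hypers: LDABGHypers, seed,
                   num_active: int | None = None) -> tuple[LDABGState, LDABGStats]:
    if corpus.num_docs == 0:
        raise ValueError("cannot initialize on an empty corpus")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if num_active is None:
        num_active = corpus.num_docs
    token_state = np.full(corpus.num_tokens, UNASSIGNED, dtype=np.int32)
    t_active = int(corpus.doc_ptr[num_active])
    token_state[:t_active] = rng.integers(0, hypers.num_topics + 1,
                                          size=t_active)
    state = LDABGState(token_state=token_state, num_active=num_active)
    return state, LDABGStats.from_state(corpus, state, hypers.num_topics)


def lda_token_conditional(d: int, n: int, corpus: EncodedCorpus,
                          state: LDABGState, stats: LDABGStats,
                          hypers: LDABGHypers) -> np.ndarray:
    """Normalized collapsed conditional (BG, TOP(0..Z-1)) for token n of doc d."""
    t = int(corpus.doc_ptr[d]) + n
    if t >= corpus.doc_ptr[d + 1]:
        raise IndexError(f"document {d} has no token {n}")
    code = int(state.token_state[t])
    v = int(corpus.words[t])
    if code == 0:
        stats.n_bg_word[v] -= 1
        stats.n_bg_sum[0] -= 1
    elif code > 0:
        k = code - 1
        stats.n_doc_topic[d, k] -= 1
        stats.n_topic_word[k, v] -= 1
        stats.n_topic_sum[k] -= 1
        stats.n_doc_top[d] -= 1
    out = np.empty(hypers.num_topics + 1)
    try:
        K.lda_token_logprobs(d, t, corpus.words, stats.n_doc_topic,
                             stats.n_topic_word, stats.n_topic_sum,
                             stats.n_bg_word, stats.n_bg_sum, stats.n_doc_top,
                             hypers.alpha, float(hypers.alpha.sum()),
                             hypers.lam, hypers.beta_flat, corpus.num_words,
                             out)
    finally:
        if code == 0:
            stats.n_bg_word[v] += 1
            stats.n_bg_sum[0] += 1
        elif code > 0:
            k = code - 1
            stats.n_doc_topic[d, k] += 1
            stats.n_topic_word[k, v] += 1
            stats.n_topic_sum[k] += 1
            stats.n_doc_top[d] += 1
    if np.any(np.isnan(out)) or np.all(np.isinf(out)):
        raise FloatingPointError(f"non-finite LDA token conditional: {out}")
    finite = out > -np.inf
    p = np.zeros_like(out)
    p[finite] = np.exp(out[finite] - out[finite].max())
    return p / p.sum()


def lda_gibbs_sweep(corpus: EncodedCorpus, state: LDABGState,
                    stats: LDABGStats, hypers: LDABGHypers, rng,
                    docs: np.ndarray | None = None) -> None:
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if docs is None:
        docs = np.arange(state.num_active, dtype=np.int64)
    n_tokens = int(np.sum(corpus.doc_ptr[docs + 1] - corpus.doc_ptr[docs]))
    uniforms = rng.random(n_tokens)
    K.lda_sweep(docs, corpus.doc_ptr, corpus.words, state.token_state,
                stats.n_doc_topic, stats.n_topic_word, stats.n_topic_sum,
                stats.n_bg_word, stats.n_bg_sum, stats.n_doc_top,
                hypers.alpha, float(hypers.alpha.sum()), hypers.lam,
                hypers.beta_flat, corpus.num_words, uniforms)


def lda_joint_log_likelihood(corpus: EncodedCorpus, state: LDABGState,
                             stats: LDABGStats, hypers: LDABGHypers) -> float:
    """Collapsed log P(w, z, l | alpha, beta, lam) for the baseline."""
    D = state.num_active
    W = corpus.num_words
    ll = 0.0
    t_active = int(corpus.doc_ptr[D])
    n_top = int(stats.n_doc_top[:D].sum())
    n_bg = t_active - n_top
    if n_top:
        if hypers.lam == 0.0:
            raise FloatingPointError("topic tokens with lam = 0")
        ll += n_top * np.log(hypers.lam)
    if n_bg:
        if hypers.lam == 1.0:
            raise FloatingPointError("background tokens with lam = 1")
        ll += n_bg * np.log(1.0 - hypers.lam)

    asum = float(hypers.alpha.sum())
    nd = stats.n_doc_topic[:D]
    ll += float(np.sum(gammaln(asum) - gammaln(asum + stats.n_doc_top[:D])))
    ll += float(np.where(nd > 0, gammaln(nd + hypers.alpha)
                         - gammaln(hypers.alpha), 0.0).sum())

    for counts, prior in ((stats.n_topic_word, hypers.beta_flat),
                          (stats.n_bg_word[None, :], hypers.beta_flat)):
        row_tot = counts.sum(axis=1)
        ll += float(np.sum(gammaln(W * prior) - gammaln(W * prior + row_tot)))
        ll += float(np.where(counts > 0, gammaln(counts + prior)
                             - gammaln(prior), 0.0).sum())
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite LDA joint log-likelihood")
    return ll


def lda_estimate_parameters(corpus: EncodedCorpus, state: LDABGState,
                            stats: LDABGStats, hypers: LDABGHypers):
    """Posterior-mean theta, phi_topic, phi_background."""
    W = corpus.num_words
    theta = ((stats.n_doc_topic + hypers.alpha)
             / (stats.n_doc_top + hypers.alpha.sum())[:, None])
    phi_topic = ((stats.n_topic_word + hypers.beta_flat)
                 / (stats.n_topic_sum + W * hypers.beta_flat)[:, None])
    phi_background = ((stats.n_bg_word + hypers.beta_flat)
                      / (stats.n_bg_sum[0] + W * hypers.beta_flat))
    return theta, phi_topic, phi_background
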
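"""The ATAM sampler core.

The model assigns every document a latent ailment a_d and every token a
composite latent state: background noise (probability 1 - lam), an
ailment word (non-background, switch x = 1), or one of Z non-ailment
topic words.  Aspects y (general/symptom/treatment) are observed.  All
multinomial parameters are collapsed out; the Gibbs sampler alternates
between the document-level ailment variable and a single block draw over
each token's Z + 2 composite states.

Token state codes: 0 background, 1 ailment word, 2 + k topic k
(see :mod:`atam._kernels`); -1 marks tokens of not-yet-activated
documents under the incremental training schedule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln

from . import _kernels as K
from .corpus import NUM_ASPECTS, EncodedCorpus
from .priors import AilmentPriorSet, AlphaSet, FixedHypers

__all__ = [
    "ATAMHypers",
    "LatentState",
    "SufficientStats",
    "init_state",
    "ailment_conditional",
    "token_conditional",
    "gibbs_sweep",
    "estimate_parameters",
    "joint_log_likelihood",
    "ParameterEstimates",
]

STATE_BG = K.BG
STATE_AIL = K.AIL
STATE_TOP0 = K.TOP0
UNASSIGNED = -1


@dataclasses.dataclass
class ATAMHypers:
    """All hyperparameters in the array layout the kernels consume.

    The Beta prior on the ailment-vs-topic switch is kept as a
    (gamma_ail, gamma_top) pair; the symmetric study setting is
    gamma_ail = gamma_top = gamma.
    """

    alpha: np.ndarray  # (A, Z)
    s: np.ndarray      # (A,)
    m: np.ndarray      # (A, W)
    sigma: float
    gamma_ail: float
    gamma_top: float
    lam: float
    beta_flat: float

    def __post_init__(self) -> None:
        self.alpha = np.ascontiguousarray(self.alpha, dtype=np.float64)
        self.s = np.ascontiguousarray(self.s, dtype=np.float64)
        self.m = np.ascontiguousarray(self.m, dtype=np.float64)

    @property
    def num_ailments(self) -> int:
        return self.alpha.shape[0]

    @property
    def num_topics(self) -> int:
        return self.alpha.shape[1]

    @property
    def num_words(self) -> int:
        return self.m.shape[1]

    @property
    def alpha_sum(self) -> np.ndarray:
        return self.alpha.sum(axis=1)

    @classmethod
    def build(cls, fixed: FixedHypers, alphas: AlphaSet,
              prior_set: AilmentPriorSet) -> "ATAMHypers":
        if alphas.alpha.shape[0] != prior_set.num_ailments:
            raise ValueError("alpha set and prior set disagree on A")
        return cls(alpha=alphas.alpha.copy(), s=prior_set.precisions.copy(),
                   m=prior_set.means.copy(), sigma=fixed.sigma,
                   gamma_ail=fixed.gamma, gamma_top=fixed.gamma,
                   lam=fixed.lam, beta_flat=fixed.beta_flat)

    def copy(self) -> "ATAMHypers":
        return ATAMHypers(alpha=self.alpha.copy(), s=self.s.copy(),
                          m=self.m.copy(), sigma=self.sigma,
                          gamma_ail=self.gamma_ail, gamma_top=self.gamma_top,
                          lam=self.lam, beta_flat=self.beta_flat)


@dataclasses.dataclass
class LatentState:
    """Per-document ailments and per-token composite states."""

    doc_ailment: np.ndarray  # int32 (D,), -1 for inactive docs
    token_state: np.ndarray  # int32 (T,), -1 for inactive docs' tokens
    num_active: int          # documents [0, num_active) participate

    def copy(self) -> "LatentState":
        return LatentState(self.doc_ailment.copy(), self.token_state.copy(),
                           self.num_active)

    def active_docs(self) -> np.ndarray:
        return np.arange(self.num_active, dtype=np.int64)


@dataclasses.dataclass
class SufficientStats:
    """Every count table the collapsed sampler maintains, with cached sums."""

    n_ail: np.ndarray        # int64 (A,)
    n_doc_topic: np.ndarray  # int64 (D, Z)
    n_topic_word: np.ndarray  # int64 (Z, W)
    n_topic_sum: np.ndarray   # int64 (Z,)
    n_aaw: np.ndarray        # int64 (A, Y, W)  ailment/aspect/word
    n_aas: np.ndarray        # int64 (A, Y)
    n_bgw: np.ndarray        # int64 (Y, W)     background/aspect/word
    n_bgs: np.ndarray        # int64 (Y,)
    n_doc_ail: np.ndarray    # int64 (D,) tokens of d in the AIL state
    n_doc_top: np.ndarray    # int64 (D,) tokens of d in any TOP state

    @classmethod
    def empty(cls, num_docs: int, num_ailments: int, num_topics: int,
              num_words: int) -> "SufficientStats":
        z = np.zeros
        return cls(
            n_ail=z(num_ailments, np.int64),
            n_doc_topic=z((num_docs, num_topics), np.int64),
            n_topic_word=z((num_topics, num_words), np.int64),
            n_topic_sum=z(num_topics, np.int64),
            n_aaw=z((num_ailments, NUM_ASPECTS, num_words), np.int64),
            n_aas=z((num_ailments, NUM_ASPECTS), np.int64),
            n_bgw=z((NUM_ASPECTS, num_words), np.int64),
            n_bgs=z(NUM_ASPECTS, np.int64),
            n_doc_ail=z(num_docs, np.int64),
            n_doc_top=z(num_docs, np.int64),
        )

    @classmethod
    def from_state(cls, corpus: EncodedCorpus, state: LatentState,
                   num_ailments: int, num_topics: int) -> "SufficientStats":
        """Independent recount of every table from the latent assignments."""
        stats = cls.empty(corpus.num_docs, num_ailments, num_topics,
                          corpus.num_words)
        active = state.doc_ailment[:state.num_active]
        if state.num_active:
            stats.n_ail[:] = np.bincount(active, minlength=num_ailments)
        ts = state.token_state
        token_doc = corpus.token_doc()
        ail_of_token = np.where(token_doc < state.num_active,
                                state.doc_ailment[token_doc], -1)

        bg = ts == STATE_BG
        np.add.at(stats.n_bgw, (corpus.aspects[bg], corpus.words[bg]), 1)
        stats.n_bgs[:] = stats.n_bgw.sum(axis=1)

        ail = ts == STATE_AIL
        np.add.at(stats.n_aaw,
                  (ail_of_token[ail], corpus.aspects[ail], corpus.words[ail]), 1)
        stats.n_aas[:] = stats.n_aaw.sum(axis=2)
        np.add.at(stats.n_doc_ail, token_doc[ail], 1)

        top = ts >= STATE_TOP0
        ks = ts[top] - STATE_TOP0
        np.add.at(stats.n_topic_word, (ks, corpus.words[top]), 1)
        stats.n_topic_sum[:] = stats.n_topic_word.sum(axis=1)
        np.add.at(stats.n_doc_topic, (token_doc[top], ks), 1)
        np.add.at(stats.n_doc_top, token_doc[top], 1)
        return stats

    def copy(self) -> "SufficientStats":
        return SufficientStats(**{f.name: getattr(self, f.name).copy()
                                  for f in dataclasses.fields(self)})

    def equals(self, other: "SufficientStats") -> bool:
        return all(np.array_equal(getattr(self, f.name), getattr(other, f.name))
                   for f in dataclasses.fields(self))

    def audit(self, corpus: EncodedCorpus, state: LatentState,
              num_ailments: int, num_topics: int) -> None:
        """Raise if any table disagrees with an independent recount."""
        fresh = SufficientStats.from_state(corpus, state, num_ailments,
                                           num_topics)
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(fresh, f.name)
            if not np.array_equal(a, b):
                idx = np.argwhere(a != b)[0]
                raise AssertionError(
                    f"sufficient-statistic {f.name} inconsistent at index "
                    f"{tuple(idx)}: stored {a[tuple(idx)]}, recount {b[tuple(idx)]}"
                )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def init_state(corpus: EncodedCorpus, hypers: ATAMHypers, seed,
               num_active: int | None = None) -> tuple[LatentState, SufficientStats]:
    """Uniform random initialization of all latent variables.

    Documents at index >= num_active (incremental schedule) are left
    unassigned and contribute no counts.
    """
    if corpus.num_docs == 0:
        raise ValueError("cannot initialize on an empty corpus")
    rng = _as_rng(seed)
    if num_active is None:
        num_active = corpus.num_docs
    doc_ailment = np.full(corpus.num_docs, UNASSIGNED, dtype=np.int32)
    token_state = np.full(corpus.num_tokens, UNASSIGNED, dtype=np.int32)
    doc_ailment[:num_active] = rng.integers(0, hypers.num_ailments,
                                            size=num_active)
    t_active = int(corpus.doc_ptr[num_active])
    token_state[:t_active] = rng.integers(0, hypers.num_topics + 2,
                                          size=t_active)
    state = LatentState(doc_ailment=doc_ailment, token_state=token_state,
                        num_active=num_active)
    stats = SufficientStats.from_state(corpus, state, hypers.num_ailments,
                                       hypers.num_topics)
    return state, stats


def _check_finite(logp: np.ndarray, what: str) -> None:
    if np.any(np.isnan(logp)) or np.all(np.isinf(logp)):
        raise FloatingPointError(f"non-finite {what} conditional: {logp}")


def ailment_conditional(d: int, corpus: EncodedCorpus, state: LatentState,
                        stats: SufficientStats, hypers: ATAMHypers) -> np.ndarray:
    """Normalized collapsed conditional P(a_d = i | everything else).

    Removes document d's contributions, evaluates the three collapsed
    factors (prevalence, grouped ailment-word predictive, topic-count
    predictive under alpha_i) in log space, restores the counts, and
    returns the normalized probability vector.
    """
    a_old = int(state.doc_ailment[d])
    K.atam_remove_doc_ailment(d, corpus.doc_ptr, corpus.words, corpus.aspects,
                              state.token_state, a_old,
                              stats.n_ail, stats.n_aaw, stats.n_aas)
    out = np.empty(hypers.num_ailments)
    try:
        K.atam_ailment_logprobs(d, corpus.doc_ptr, corpus.words, corpus.aspects,
                                state.token_state, stats.n_ail,
                                stats.n_doc_topic, stats.n_aaw, stats.n_aas,
                                hypers.alpha, hypers.alpha_sum, hypers.s,
                                hypers.m, hypers.sigma, out)
    finally:
        K.atam_add_doc_ailment(d, corpus.doc_ptr, corpus.words, corpus.aspects,
                               state.token_state, a_old,
                               stats.n_ail, stats.n_aaw, stats.n_aas)
    _check_finite(out, "ailment")
    out -= out.max()
    p = np.exp(out)
    return p / p.sum()


def token_conditional(d: int, n: int, corpus: EncodedCorpus, state: LatentState,
                      stats: SufficientStats, hypers: ATAMHypers,
                      mask_ail: bool = False) -> np.ndarray:
    """Normalized collapsed conditional over token n of document d.

    Returns a vector of length Z + 2 ordered (BG, AIL, TOP(0..Z-1)).
    With mask_ail the AIL branch is forbidden and the switch factor
    dropped, reducing the conditional to LDA-with-background.
    """
    t = int(corpus.doc_ptr[d]) + n
    if t >= corpus.doc_ptr[d + 1]:
        raise IndexError(f"document {d} has no token {n}")
    i = int(state.doc_ailment[d])
    code = int(state.token_state[t])
    K.atam_remove_token(d, t, code, i, corpus.words, corpus.aspects,
                        stats.n_doc_topic, stats.n_topic_word, stats.n_topic_sum,
                        stats.n_aaw, stats.n_aas, stats.n_bgw, stats.n_bgs,
                        stats.n_doc_ail, stats.n_doc_top)
    out = np.empty(hypers.num_topics + 2)
    try:
        K.atam_token_logprobs(d, t, i, corpus.words, corpus.aspects,
                              stats.n_doc_topic, stats.n_topic_word,
                              stats.n_topic_sum, stats.n_aaw, stats.n_aas,
                              stats.n_bgw, stats.n_bgs, stats.n_doc_ail,
                              stats.n_doc_top, hypers.alpha, hypers.alpha_sum,
                              hypers.s, hypers.m, hypers.gamma_ail,
                              hypers.gamma_top, hypers.lam, hypers.beta_flat,
                              corpus.num_words, mask_ail, out)
    finally:
        K.atam_add_token(d, t, code, i, corpus.words, corpus.aspects,
                         stats.n_doc_topic, stats.n_topic_word,
                         stats.n_topic_sum, stats.n_aaw, stats.n_aas,
                         stats.n_bgw, stats.n_bgs, stats.n_doc_ail,
                         stats.n_doc_top)
    _check_finite(out, "token")
    finite = out > -np.inf
    p = np.zeros_like(out)
    p[finite] = np.exp(out[finite] - out[finite].max())
    return p / p.sum()


def gibbs_sweep(corpus: EncodedCorpus, state: LatentState,
                stats: SufficientStats, hypers: ATAMHypers, rng,
                docs: np.ndarray | None = None,
                sample_docs: bool = True) -> None:
    """One in-place Gibbs sweep over the active documents."""
    rng = _as_rng(rng)
    if docs is None:
        docs = state.active_docs()
    n_tokens = int(np.sum(corpus.doc_ptr[docs + 1] - corpus.doc_ptr[docs]))
    n_draws = (len(docs) if sample_docs else 0) + n_tokens
    uniforms = rng.random(n_draws)
    K.atam_sweep(docs, corpus.doc_ptr, corpus.words, corpus.aspects,
                 state.doc_ailment, state.token_state,
                 stats.n_ail, stats.n_doc_topic, stats.n_topic_word,
                 stats.n_topic_sum, stats.n_aaw, stats.n_aas,
                 stats.n_bgw, stats.n_bgs, stats.n_doc_ail, stats.n_doc_top,
                 hypers.alpha, hypers.alpha_sum, hypers.s, hypers.m,
                 hypers.sigma, hypers.gamma_ail, hypers.gamma_top,
                 hypers.lam, hypers.beta_flat, corpus.num_words,
                 uniforms, sample_docs)


@dataclasses.dataclass
class ParameterEstimates:
    """Posterior-mean point estimates given the collapsed counts."""

    eta: np.ndarray            # (A,)
    pi: np.ndarray             # (D,)
    theta: np.ndarray          # (D, Z)
    phi_topic: np.ndarray      # (Z, W)
    phi_ailment: np.ndarray    # (A, Y, W)
    phi_background: np.ndarray  # (Y, W)


def estimate_parameters(corpus: EncodedCorpus, state: LatentState,
                        stats: SufficientStats,
                        hypers: ATAMHypers) -> ParameterEstimates:
    """Dirichlet/Beta posterior means of every model parameter."""
    A, Z, W = hypers.num_ailments, hypers.num_topics, corpus.num_words
    D = corpus.num_docs
    eta = (stats.n_ail + hypers.sigma) / (state.num_active + A * hypers.sigma)
    pi = ((stats.n_doc_ail + hypers.gamma_ail)
          / (stats.n_doc_ail + stats.n_doc_top + hypers.gamma_ail + hypers.gamma_top))
    alpha_doc = np.where(state.doc_ailment[:, None] >= 0,
                         hypers.alpha[np.clip(state.doc_ailment, 0, A - 1)],
                         np.full((D, Z), 1.0 / Z))
    theta = ((stats.n_doc_topic + alpha_doc)
             / (stats.n_doc_top + alpha_doc.sum(axis=1))[:, None])
    phi_topic = ((stats.n_topic_word + hypers.beta_flat)
                 / (stats.n_topic_sum + W * hypers.beta_flat)[:, None])
    phi_ailment = ((stats.n_aaw + hypers.s[:, None, None] * hypers.m[:, None, :])
                   / (stats.n_aas + hypers.s[:, None])[:, :, None])
    phi_background = ((stats.n_bgw + hypers.beta_flat)
                      / (stats.n_bgs + W * hypers.beta_flat)[:, None])
    return ParameterEstimates(eta=eta, pi=pi, theta=theta, phi_topic=phi_topic,
                              phi_ailment=phi_ailment,
                              phi_background=phi_background)


def _dm_table_term(counts: np.ndarray, prior: np.ndarray) -> float:
    """log [ B(counts + prior) / B(prior) ] summed over rows.

    counts: (R, W) rows each under a Dirichlet prior; prior broadcastable.
    """
    counts = np.asarray(counts, dtype=np.float64)
    prior = np.broadcast_to(prior, counts.shape)
    row_prior = prior.sum(axis=-1)
    row_tot = counts.sum(axis=-1) + row_prior
    term = gammaln(row_prior) - gammaln(row_tot)
    term = term + np.where(counts > 0,
                           gammaln(counts + prior) - gammaln(prior), 0.0).sum(axis=-1)
    return float(term.sum())


def joint_log_likelihood(corpus: EncodedCorpus, state: LatentState,
                         stats: SufficientStats, hypers: ATAMHypers) -> float:
    """Collapsed log P(w, a, z, x, l | alpha, beta, sigma, gamma, lam).

    Sum of Dirichlet-multinomial normalizer ratios for every count table
    plus the Bernoulli background terms; the objective that
    hyperparameter optimization must not degrade.
    """
    A, Z = hypers.num_ailments, hypers.num_topics
    D = state.num_active
    W = corpus.num_words
    ll = 0.0

    # ailment prevalence (Dirichlet-multinomial over a)
    ll += _dm_table_term(stats.n_ail[None, :], np.full(A, hypers.sigma))

    # Bernoulli switch l: background vs not
    t_active = int(corpus.doc_ptr[D])
    n_nonbg = int(stats.n_doc_ail[:D].sum() + stats.n_doc_top[:D].sum())
    n_bg = t_active - n_nonbg
    if n_nonbg:
        if hypers.lam == 0.0:
            raise FloatingPointError("non-background tokens with lam = 0")
        ll += n_nonbg * np.log(hypers.lam)
    if n_bg:
        if hypers.lam == 1.0:
            raise FloatingPointError("background tokens with lam = 1")
        ll += n_bg * np.log(1.0 - hypers.lam)

    # per-document Beta-Bernoulli for the ailment-vs-topic switch x
    ga, gt = hypers.gamma_ail, hypers.gamma_top
    na, nt = stats.n_doc_ail[:D], stats.n_doc_top[:D]
    ll += float(np.sum(gammaln(na + ga) + gammaln(nt + gt)
                       - gammaln(na + nt + ga + gt)
                       - gammaln(ga) - gammaln(gt) + gammaln(ga + gt)))

    # per-document topic counts under alpha_{a_d}
    a = state.doc_ailment[:D]
    alpha_doc = hypers.alpha[a]
    asum = hypers.alpha_sum[a]
    nd = stats.n_doc_topic[:D]
    ll += float(np.sum(gammaln(asum) - gammaln(asum + nt)))
    ll += float(np.where(nd > 0, gammaln(nd + alpha_doc) - gammaln(alpha_doc),
                         0.0).sum())

    # word tables
    ll += _dm_table_term(stats.n_topic_word, np.full(W, hypers.beta_flat))
    ll += _dm_table_term(stats.n_bgw, np.full(W, hypers.beta_flat))
    beta_ail = hypers.s[:, None, None] * hypers.m[:, None, :]
    ll += _dm_table_term(stats.n_aaw,
                         np.broadcast_to(beta_ail, stats.n_aaw.shape))

    if not np.isfinite(ll):
        raise FloatingPointError("non-finite joint log-likelihood")
    return ll
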
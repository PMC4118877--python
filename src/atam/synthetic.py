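"""Synthetic corpora drawn from the ATAM generative story.

Generates documents with known eta, alpha, phi parameters and returns
the true latent assignments, so inference can be scored for parameter
recovery without any external data.  Aspect labels are produced either
directly from a per-ailment categorical over
{general, symptom, treatment}, or (lexicon-mediated mode) by emitting
surface phrases from aspect-tagged phrase pools so that
:func:`atam.corpus.label_aspects` reproduces the labels exactly.
Optional per-ailment temporal or regional intensities plant trends in
the metadata for the trend-mining layer to recover.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corpus import NUM_ASPECTS, Aspect, Corpus, Document, Token, Vocabulary
from .model import STATE_AIL, STATE_BG, STATE_TOP0, LatentState, ParameterEstimates

__all__ = [
    "TrueParams",
    "GeneratedCorpus",
    "generate_corpus",
    "match_components",
    "recovery_report",
]


@dataclasses.dataclass
class TrueParams:
    """Ground-truth generating parameters.

    Defaults mirror the modelling setup: lam = 0.2 means 80% of tokens
    are background noise; gamma = 1 gives each document a uniform random
    ailment-vs-topic mixing weight; aspect_probs defaults to 0.7 general
    / 0.2 symptom / 0.1 treatment per token.
    """

    eta: np.ndarray             # (A,)
    alpha: np.ndarray           # (A, Z)
    phi_ailment: np.ndarray     # (A, Y, W)
    phi_topic: np.ndarray       # (Z, W)
    phi_background: np.ndarray  # (Y, W)
    lam: float = 0.2
    gamma: float = 1.0
    aspect_probs: np.ndarray | None = None       # (A, Y)
    temporal_intensity: np.ndarray | None = None  # (A, B) unnormalized
    region_intensity: np.ndarray | None = None    # (A, R)
    region_codes: list[str] | None = None
    bin_start: _dt.date = _dt.date(2011, 10, 2)
    bin_days: int = 7

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=np.float64)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.phi_ailment = np.asarray(self.phi_ailment, dtype=np.float64)
        self.phi_topic = np.asarray(self.phi_topic, dtype=np.float64)
        self.phi_background = np.asarray(self.phi_background, dtype=np.float64)
        A = self.eta.shape[0]
        if self.aspect_probs is None:
            self.aspect_probs = np.tile([0.7, 0.2, 0.1], (A, 1))
        self.aspect_probs = np.asarray(self.aspect_probs, dtype=np.float64)
        W = self.phi_topic.shape[1]
        if (self.phi_ailment.shape != (A, NUM_ASPECTS, W)
                or self.alpha.shape[0] != A
                or self.phi_background.shape != (NUM_ASPECTS, W)
                or self.aspect_probs.shape != (A, NUM_ASPECTS)):
            raise ValueError("parameter dimensions are inconsistent")
        for arr in (self.eta[None, :], self.aspect_probs,
                    self.phi_topic, self.phi_background,
                    self.phi_ailment.reshape(-1, W)):
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-8):
                raise ValueError("distribution rows must sum to 1")

    @property
    def num_ailments(self) -> int:
        return self.eta.shape[0]

    @property
    def num_topics(self) -> int:
        return self.phi_topic.shape[0]

    @property
    def num_words(self) -> int:
        return self.phi_topic.shape[1]

    @classmethod
    def well_separated(cls, num_ailments: int = 3, num_topics: int = 3,
                       num_words: int = 200, seed: int = 0,
                       block_mass: float = 0.95, lam: float = 0.5,
                       **kwargs) -> "TrueParams":
        """Block-structured parameters: each ailment and each topic owns a
        disjoint vocabulary block holding `block_mass` of its word
        probability; the background spreads over the remaining words.
        """
        rng = np.random.default_rng(seed)
        A, Z, W = num_ailments, num_topics, num_words
        n_blocks = A + Z
        block = W // (n_blocks + 1)
        if block < 4:
            raise ValueError("num_words too small for block structure")

        def block_dist(lo: int, hi: int) -> np.ndarray:
            p = np.full(W, (1.0 - block_mass) / (W - (hi - lo)))
            inner = rng.dirichlet(np.full(hi - lo, 2.0)) * block_mass
            p[lo:hi] = inner
            return p

        phi_ailment = np.empty((A, NUM_ASPECTS, W))
        for i in range(A):
            lo, hi = i * block, (i + 1) * block
            third = (hi - lo) // 3
            # aspects concentrate on different thirds of the ailment block
            for j in range(NUM_ASPECTS):
                jlo = lo + j * third
                jhi = hi if j == NUM_ASPECTS - 1 else jlo + third
                phi_ailment[i, j] = block_dist(jlo, jhi)
        phi_topic = np.empty((Z, W))
        for k in range(Z):
            lo = (A + k) * block
            phi_topic[k] = block_dist(lo, lo + block)
        bg_lo = n_blocks * block
        phi_background = np.stack([block_dist(bg_lo, W) for _ in range(NUM_ASPECTS)])

        eta = rng.dirichlet(np.full(A, 20.0))
        alpha = rng.dirichlet(np.full(Z, 2.0), size=A) * 5.0
        return cls(eta=eta, alpha=alpha, phi_ailment=phi_ailment,
                   phi_topic=phi_topic, phi_background=phi_background,
                   lam=lam, **kwargs)


@dataclasses.dataclass
class GeneratedCorpus:
    corpus: Corpus
    state: LatentState            # true assignments, corpus encoding order
    pi: np.ndarray                # true per-document ailment-word weight
    theta: np.ndarray             # true per-document topic distributions
    bin_of_doc: np.ndarray | None  # temporal bin index per document, if planted
    bin_ailment_probs: np.ndarray | None  # (B, A) planted P(a | bin)


def generate_corpus(params: TrueParams, num_docs: int, doc_length: int,
                    seed: int) -> GeneratedCorpus:
    """Sample a corpus exactly as the generative story prescribes.

    Per document: a_d ~ Cat(eta) (modulated by the planted intensity of
    the document's time bin, when configured), theta_d ~ Dir(alpha_{a_d}),
    pi_d ~ Beta(gamma, gamma).  Per token: aspect y ~ aspect_probs[a_d],
    l ~ Bern(lam); background tokens draw the word from phi_background[y],
    non-background tokens draw x ~ Bern(pi_d) and the word from
    phi_ailment[a_d, y] (x = 1) or from phi_topic[z], z ~ theta_d (x = 0).
    """
    rng = np.random.default_rng(seed)
    A, Z, W = params.num_ailments, params.num_topics, params.num_words
    vocab = Vocabulary(f"w{v:04d}" for v in range(W))

    bins = None
    bin_probs = None
    if params.temporal_intensity is not None:
        B = params.temporal_intensity.shape[1]
        bins = rng.integers(0, B, size=num_docs)
        bins.sort()
        raw = params.eta[:, None] * params.temporal_intensity  # (A, B)
        bin_probs = (raw / raw.sum(axis=0)).T                  # (B, A)

    regions = None
    if params.region_intensity is not None:
        R = params.region_intensity.shape[1]
        regions = rng.integers(0, R, size=num_docs)

    doc_ailment = np.empty(num_docs, dtype=np.int32)
    token_state = np.empty(num_docs * doc_length, dtype=np.int32)
    pi = rng.beta(params.gamma, params.gamma, size=num_docs)
    theta = np.empty((num_docs, Z))
    documents: list[Document] = []
    t = 0
    for d in range(num_docs):
        if bins is not None:
            p_a = bin_probs[bins[d]]
        elif regions is not None:
            raw = params.eta * params.region_intensity[:, regions[d]]
            p_a = raw / raw.sum()
        else:
            p_a = params.eta
        a = rng.choice(A, p=p_a)
        doc_ailment[d] = a
        theta[d] = rng.dirichlet(params.alpha[a])
        tokens: list[Token] = []
        for _ in range(doc_length):
            j = rng.choice(NUM_ASPECTS, p=params.aspect_probs[a])
            if rng.random() >= params.lam:
                token_state[t] = STATE_BG
                v = rng.choice(W, p=params.phi_background[j])
            elif rng.random() < pi[d]:
                token_state[t] = STATE_AIL
                v = rng.choice(W, p=params.phi_ailment[a, j])
            else:
                k = rng.choice(Z, p=theta[d])
                token_state[t] = STATE_TOP0 + k
                v = rng.choice(W, p=params.phi_topic[k])
            tokens.append(Token(word_id=int(v), aspect=Aspect(j),
                                surface=vocab.word(int(v))))
            t += 1
        ts = None
        if bins is not None:
            ts = params.bin_start + _dt.timedelta(days=params.bin_days * int(bins[d]))
        region = (params.region_codes[regions[d]]
                  if regions is not None and params.region_codes is not None
                  else (f"R{regions[d]:02d}" if regions is not None else None))
        documents.append(Document(doc_id=f"d{d:06d}", tokens=tokens,
                                  timestamp=ts, region=region))
    corpus = Corpus(documents=documents, vocab=vocab,
                    meta={"synthetic": True, "seed": seed})
    state = LatentState(doc_ailment=doc_ailment, token_state=token_state,
                        num_active=num_docs)
    return GeneratedCorpus(corpus=corpus, state=state, pi=pi, theta=theta,
                           bin_of_doc=bins, bin_ailment_probs=bin_probs)


def match_components(true_dists: np.ndarray,
                     est_dists: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal matching of estimated to true components by total L1 distance.

    Rows beyond the first axis are flattened.  Returns (perm, cost) where
    perm[i] is the estimated component matched to true component i.
    """
    true_flat = np.asarray(true_dists).reshape(true_dists.shape[0], -1)
    est_flat = np.asarray(est_dists).reshape(est_dists.shape[0], -1)
    if true_flat.shape[0] != est_flat.shape[0]:
        raise ValueError("component counts differ")
    cost = np.abs(true_flat[:, None, :] - est_flat[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(true_flat.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm, float(cost[rows, cols].sum())


def recovery_report(truth: GeneratedCorpus, params: TrueParams,
                    estimates: ParameterEstimates,
                    est_doc_ailment: np.ndarray) -> dict:
    """Score estimated parameters and assignments against the ground truth.

    Ailment components are matched by their (flattened) aspect-conditioned
    word distributions, topics by their word distributions; reports the
    document-ailment accuracy under the matching, mean L1 distances of
    matched rows, and the maximum absolute error of the recovered
    prevalence eta.
    """
    ail_perm, _ = match_components(params.phi_ailment, estimates.phi_ailment)
    top_perm, _ = match_components(params.phi_topic, estimates.phi_topic)
    A = params.num_ailments
    # map estimated ailment labels back to true component indexing
    inverse = np.empty(A, dtype=np.int64)
    inverse[ail_perm] = np.arange(A)
    accuracy = float(np.mean(inverse[est_doc_ailment]
                             == truth.state.doc_ailment))
    phi_a_l1 = float(np.mean(np.abs(params.phi_ailment
                                    - estimates.phi_ailment[ail_perm])
                             .sum(axis=-1)))
    phi_t_l1 = float(np.mean(np.abs(params.phi_topic
                                    - estimates.phi_topic[top_perm])
                             .sum(axis=-1)))
    eta_err = float(np.max(np.abs(params.eta - estimates.eta[ail_perm])))
    return {
        "doc_ailment_accuracy": accuracy,
        "phi_ailment_mean_l1": phi_a_l1,
        "phi_topic_mean_l1": phi_t_l1,
        "eta_max_abs_error": eta_err,
        "ailment_permutation": ail_perm.tolist(),
        "topic_permutation": top_perm.tolist(),
    }
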
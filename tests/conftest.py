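"""Shared fixtures and helpers for building tiny random instances."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from atam.corpus import Aspect, Corpus, Document, Token, Vocabulary
from atam.model import ATAMHypers


def make_corpus(doc_words, doc_aspects, num_words):
    """Build a Corpus from per-document word-id and aspect-code lists."""
    vocab = Vocabulary(f"w{v}" for v in range(num_words))
    docs = []
    for d, (ws, ys) in enumerate(zip(doc_words, doc_aspects)):
        tokens = [Token(word_id=w, aspect=Aspect(y), surface=vocab.word(w))
                  for w, y in zip(ws, ys)]
        docs.append(Document(doc_id=f"d{d}", tokens=tokens))
    return Corpus(documents=docs, vocab=vocab)


def random_tiny_instance(rng, num_ailments=2, num_topics=2, num_words=4,
                         num_docs=3, max_len=4):
    """Random tiny corpus + random asymmetric hyperparameters.

    Returns (doc_words, doc_aspects, encoded corpus, ATAMHypers, kwargs
    for the test oracles).
    """
    doc_words = [list(rng.integers(0, num_words,
                                   size=rng.integers(1, max_len + 1)))
                 for _ in range(num_docs)]
    doc_aspects = [list(rng.integers(0, 3, size=len(ws))) for ws in doc_words]
    corpus = make_corpus(doc_words, doc_aspects, num_words)
    enc = corpus.encode()

    m = rng.dirichlet(np.full(num_words, 0.8), size=num_ailments)
    s = rng.uniform(0.5, 8.0, size=num_ailments)
    alpha = rng.uniform(0.2, 2.0, size=(num_ailments, num_topics))
    hypers = ATAMHypers(alpha=alpha, s=s, m=m,
                        sigma=float(rng.uniform(0.3, 2.0)),
                        gamma_ail=float(rng.uniform(0.3, 2.0)),
                        gamma_top=float(rng.uniform(0.3, 2.0)),
                        lam=float(rng.uniform(0.1, 0.9)),
                        beta_flat=float(rng.uniform(0.05, 1.0)))
    oracle_kw = dict(num_ailments=num_ailments, num_topics=num_topics,
                     num_words=num_words, m=m.tolist(), s=s.tolist(),
                     alpha=alpha.tolist(), sigma=hypers.sigma,
                     gamma_ail=hypers.gamma_ail, gamma_top=hypers.gamma_top,
                     lam=hypers.lam, beta_flat=hypers.beta_flat)
    return doc_words, doc_aspects, enc, hypers, oracle_kw


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
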
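"""Corpus handling: tokenization, aspect labeling, vocabulary, serialization.

Documents are short informal texts (tweets and the like) with optional
timestamp and region metadata.  Every token carries an observed *aspect*
label in {general, symptom, treatment}, assigned before inference by
greedy keyphrase matching against a symptom/treatment lexicon.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import unicodedata
from collections import Counter
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Aspect",
    "Token",
    "Document",
    "Vocabulary",
    "KeyphraseLexicon",
    "Corpus",
    "EncodedCorpus",
    "tokenize",
    "label_aspects",
    "contains_url",
    "load_corpus",
    "save_corpus_cache",
    "load_corpus_cache",
]


class Aspect(IntEnum):
    """Observed per-token label: is the word a symptom, a treatment, or neither."""

    GENERAL = 0
    SYMPTOM = 1
    TREATMENT = 2


NUM_ASPECTS = 3

_ASPECT_NAMES = {"general": Aspect.GENERAL, "symptom": Aspect.SYMPTOM,
                 "treatment": Aspect.TREATMENT}


def _is_punct(ch: str) -> bool:
    # Unicode punctuation (P*) and symbols (S*); informal text is unicode-rich.
    return unicodedata.category(ch)[0] in ("P", "S")


def tokenize(text: str) -> list[str]:
    """Lower-case and split *text* into word tokens and punctuation-run tokens.

    Maximal contiguous runs of punctuation/symbol characters act as word
    separators but are kept as tokens in their own right; whitespace is
    never emitted.

    >>> tokenize("damn flu, home with a fever watching TV.")
    ['damn', 'flu', ',', 'home', 'with', 'a', 'fever', 'watching', 'tv', '.']
    """
    tokens: list[str] = []
    buf: list[str] = []
    mode: str | None = None  # 'w' word run, 'p' punctuation run

    def flush() -> None:
        if buf:
            tokens.append("".join(buf))
            buf.clear()

    for ch in text.lower():
        if ch.isspace():
            flush()
            mode = None
            continue
        kind = "p" if _is_punct(ch) else "w"
        if kind != mode:
            flush()
            mode = kind
        buf.append(ch)
    flush()
    return tokens


def contains_url(text: str) -> bool:
    """True if any whitespace-separated chunk looks like a URL."""
    return any(
        chunk.startswith(("http://", "https://", "www."))
        for chunk in text.lower().split()
    )


class Vocabulary:
    """Bijective word-string <-> dense integer id map."""

    def __init__(self, words: Iterable[str] = ()) -> None:
        self._id2word: list[str] = []
        self._word2id: dict[str, int] = {}
        for w in words:
            self.add(w)

    def add(self, word: str) -> int:
        wid = self._word2id.get(word)
        if wid is None:
            wid = len(self._id2word)
            self._word2id[word] = wid
            self._id2word.append(word)
        return wid

    def get(self, word: str) -> int | None:
        return self._word2id.get(word)

    def __getitem__(self, word: str) -> int:
        return self._word2id[word]

    def word(self, wid: int) -> str:
        return self._id2word[wid]

    def __len__(self) -> int:
        return len(self._id2word)

    def __contains__(self, word: str) -> bool:
        return word in self._word2id

    def __iter__(self):
        return iter(self._id2word)

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocabulary) and self._id2word == other._id2word


@dataclasses.dataclass
class Token:
    word_id: int
    aspect: Aspect
    surface: str


@dataclasses.dataclass
class Document:
    doc_id: str
    tokens: list[Token]
    timestamp: _dt.date | None = None
    region: str | None = None

    def __len__(self) -> int:
        return len(self.tokens)


class KeyphraseLexicon:
    """Maps tokenized phrases to an aspect category (symptom or treatment).

    Phrases are stored tokenized with :func:`tokenize` so that matching
    against tokenized documents is exact.  A phrase seen with two
    categories keeps its first category (the conflict is logged).
    """

    def __init__(self) -> None:
        self._phrases: dict[tuple[str, ...], Aspect] = {}
        self.max_len = 0

    def add(self, phrase: str | Sequence[str], aspect: Aspect) -> None:
        key = tuple(tokenize(phrase)) if isinstance(phrase, str) else tuple(phrase)
        if not key:
            return
        existing = self._phrases.get(key)
        if existing is not None:
            if existing != aspect:
                logger.warning(
                    "lexicon conflict for %r: keeping %s, ignoring %s",
                    " ".join(key), existing.name, aspect.name,
                )
            return
        self._phrases[key] = aspect
        self.max_len = max(self.max_len, len(key))

    def lookup(self, ngram: tuple[str, ...]) -> Aspect | None:
        return self._phrases.get(ngram)

    def __len__(self) -> int:
        return len(self._phrases)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeyphraseLexicon":
        """Load a two-column TSV (phrase, category); '#'-comment lines allowed."""
        lex = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    logger.warning("lexicon line %d malformed, skipped: %r", lineno, line)
                    continue
                phrase, category = parts
                cat = _ASPECT_NAMES.get(category.strip().lower())
                if cat is None or cat == Aspect.GENERAL:
                    logger.warning("lexicon line %d: unknown category %r, skipped",
                                   lineno, category)
                    continue
                lex.add(phrase, cat)
        return lex

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Aspect]) -> "KeyphraseLexicon":
        lex = cls()
        for phrase, aspect in mapping.items():
            lex.add(phrase, aspect)
        return lex


def label_aspects(tokens: Sequence[str], lexicon: KeyphraseLexicon | None) -> list[Aspect]:
    """Assign each token an aspect by greedy longest-match left-to-right.

    Every token inside a matched lexicon phrase receives that phrase's
    category; tokens consumed by a match are not re-matched; everything
    else is GENERAL.
    """
    labels = [Aspect.GENERAL] * len(tokens)
    if lexicon is None or len(lexicon) == 0:
        return labels
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(lexicon.max_len, n - i), 0, -1):
            aspect = lexicon.lookup(tuple(tokens[i:i + length]))
            if aspect is not None:
                for k in range(i, i + length):
                    labels[k] = aspect
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return labels


@dataclasses.dataclass
class Corpus:
    documents: list[Document]
    vocab: Vocabulary
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def num_docs(self) -> int:
        return len(self.documents)

    @property
    def num_words(self) -> int:
        return len(self.vocab)

    def encode(self) -> "EncodedCorpus":
        """Flatten to the CSR-style arrays the sampler kernels operate on."""
        lengths = np.fromiter((len(d) for d in self.documents), dtype=np.int64,
                              count=len(self.documents))
        doc_ptr = np.zeros(len(self.documents) + 1, dtype=np.int64)
        np.cumsum(lengths, out=doc_ptr[1:])
        total = int(doc_ptr[-1])
        words = np.empty(total, dtype=np.int32)
        aspects = np.empty(total, dtype=np.int8)
        pos = 0
        for doc in self.documents:
            for tok in doc.tokens:
                words[pos] = tok.word_id
                aspects[pos] = int(tok.aspect)
                pos += 1
        return EncodedCorpus(doc_ptr=doc_ptr, words=words, aspects=aspects,
                             num_words=len(self.vocab))


@dataclasses.dataclass
class EncodedCorpus:
    """Flat token arrays: ``words[doc_ptr[d]:doc_ptr[d+1]]`` are document d's tokens."""

    doc_ptr: np.ndarray  # int64, length D+1
    words: np.ndarray    # int32, length T
    aspects: np.ndarray  # int8, length T
    num_words: int

    @property
    def num_docs(self) -> int:
        return len(self.doc_ptr) - 1

    @property
    def num_tokens(self) -> int:
        return int(self.doc_ptr[-1])

    def doc_lengths(self) -> np.ndarray:
        return np.diff(self.doc_ptr)

    def token_doc(self) -> np.ndarray:
        """Document index of every token."""
        return np.repeat(np.arange(self.num_docs), self.doc_lengths())


def _parse_record(line: str) -> dict:
    rec = json.loads(line)
    if not isinstance(rec, dict) or "text" not in rec:
        raise ValueError("record must be a JSON object with a 'text' field")
    return rec


def load_corpus(
    path: str | Path,
    lexicon: KeyphraseLexicon | None = None,
    drop_urls: bool = True,
    min_df: int = 1,
    vocab: Vocabulary | None = None,
) -> Corpus:
    """Load a JSON-lines corpus, tokenize, aspect-label, and build the vocabulary.

    Each line is ``{"id": str, "text": str, "timestamp": "YYYY-MM-DD"?,
    "region": str?}``.  Records containing a URL are dropped when
    *drop_urls* is set; malformed records are skipped with a logged line
    number.  Words appearing in fewer than *min_df* documents are pruned
    from the retained documents.  If *vocab* is given it is frozen:
    unseen words are skipped with a warning (inference-time loading).
    """
    raw: list[tuple[str, list[str], list[Aspect], _dt.date | None, str | None]] = []
    skipped = 0
    dropped_urls = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = _parse_record(line)
            except (json.JSONDecodeError, ValueError) as exc:
                logger.warning("line %d malformed, skipped: %s", lineno, exc)
                skipped += 1
                continue
            text = rec["text"]
            if drop_urls and contains_url(text):
                dropped_urls += 1
                continue
            toks = tokenize(text)
            labels = label_aspects(toks, lexicon)
            ts = None
            if rec.get("timestamp"):
                try:
                    ts = _dt.date.fromisoformat(rec["timestamp"])
                except ValueError:
                    logger.warning("line %d bad timestamp %r, ignored", lineno,
                                   rec["timestamp"])
            raw.append((str(rec.get("id", lineno)), toks, labels, ts,
                        rec.get("region")))
    if skipped:
        logger.info("skipped %d malformed records", skipped)
    if dropped_urls:
        logger.info("dropped %d URL-bearing records", dropped_urls)

    frozen = vocab is not None
    if vocab is None:
        vocab = Vocabulary()
        if min_df > 1:
            df: Counter[str] = Counter()
            for _, toks, _, _, _ in raw:
                df.update(set(toks))
            kept = {w for w, c in df.items() if c >= min_df}
        else:
            kept = None
    else:
        kept = None

    documents: list[Document] = []
    unseen = 0
    for doc_id, toks, labels, ts, region in raw:
        tokens: list[Token] = []
        for surf, asp in zip(toks, labels):
            if frozen:
                wid = vocab.get(surf)
                if wid is None:
                    unseen += 1
                    continue
            else:
                if kept is not None and surf not in kept:
                    continue
                wid = vocab.add(surf)
            tokens.append(Token(word_id=wid, aspect=asp, surface=surf))
        documents.append(Document(doc_id=doc_id, tokens=tokens,
                                  timestamp=ts, region=region))
    if unseen:
        logger.warning("skipped %d tokens outside the frozen vocabulary", unseen)
    return Corpus(documents=documents, vocab=vocab,
                  meta={"source": str(path), "skipped": skipped,
                        "dropped_urls": dropped_urls})


def save_corpus_cache(corpus: Corpus, path: str | Path) -> None:
    """Serialize a tokenized corpus (word ids + aspect codes) as JSON-lines.

    The first line holds the vocabulary; subsequent lines one document each.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"vocab": list(corpus.vocab), "meta": corpus.meta}) + "\n")
        for doc in corpus.documents:
            rec = {
                "id": doc.doc_id,
                "w": [t.word_id for t in doc.tokens],
                "y": [int(t.aspect) for t in doc.tokens],
            }
            if doc.timestamp is not None:
                rec["timestamp"] = doc.timestamp.isoformat()
            if doc.region is not None:
                rec["region"] = doc.region
            fh.write(json.dumps(rec) + "\n")


def load_corpus_cache(path: str | Path) -> Corpus:
    with open(path, encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        vocab = Vocabulary(header["vocab"])
        documents = []
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            ts = (_dt.date.fromisoformat(rec["timestamp"])
                  if "timestamp" in rec else None)
            tokens = [Token(word_id=w, aspect=Aspect(y), surface=vocab.word(w))
                      for w, y in zip(rec["w"], rec["y"])]
            documents.append(Document(doc_id=rec["id"], tokens=tokens,
                                      timestamp=ts, region=rec.get("region")))
    return Corpus(documents=documents, vocab=vocab, meta=header.get("meta", {}))
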
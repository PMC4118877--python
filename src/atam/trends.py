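"""Temporal and geographic trend mining from model assignments.

Turns document-level ailment assignments plus timestamp/region metadata
into rate series P(a = i | time bin) or P(a = i | region) — the fraction
of documents in the bin assigned to the ailment — together with
keyword-count baseline series, z-score standardization, and Pearson
correlation against external surveillance series.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .corpus import Corpus, tokenize
from .lda_bg import LDABGStats

logger = logging.getLogger(__name__)

__all__ = [
    "TrendSeries",
    "week_start",
    "ailment_rate",
    "keyword_rate",
    "assign_topic_lda",
    "pearson",
    "zscore",
    "load_external_series",
]


@dataclasses.dataclass
class TrendSeries:
    """Rate per bin with the document-count denominator.

    Bins are sorted, unique identifiers (ISO week-start dates, "YYYY-MM"
    months, or region codes); empty bins are never emitted.
    """

    bins: list
    rates: np.ndarray
    denominators: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.denominators = np.asarray(self.denominators, dtype=np.int64)
        if not (len(self.bins) == len(self.rates) == len(self.denominators)):
            raise ValueError("bins, rates, denominators must align")
        if len(set(self.bins)) != len(self.bins):
            raise ValueError("bins must be unique")
        if np.any(self.denominators <= 0):
            raise ValueError("every emitted bin needs a positive denominator")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bins, "rate": self.rates,
                             "n": self.denominators})


def week_start(day: _dt.date, week_starts_on: int = 6) -> _dt.date:
    """First day of `day`'s week; weeks start on Sunday by default
    (weekday 6), matching surveillance-week conventions."""
    offset = (day.weekday() - week_starts_on) % 7
    return day - _dt.timedelta(days=offset)


def _bin_key(doc, binning: str):
    if binning == "region":
        return doc.region
    if doc.timestamp is None:
        return None
    if binning == "week":
        return week_start(doc.timestamp).isoformat()
    if binning == "month":
        return f"{doc.timestamp.year:04d}-{doc.timestamp.month:02d}"
    raise ValueError(f"unknown binning {binning!r}")


def _rate_series(corpus: Corpus, binning: str, hits) -> TrendSeries:
    num = {}
    den = {}
    excluded = 0
    for d, doc in enumerate(corpus.documents):
        key = _bin_key(doc, binning)
        if key is None:
            excluded += 1
            continue
        den[key] = den.get(key, 0) + 1
        if hits(d, doc):
            num[key] = num.get(key, 0) + 1
    if excluded:
        logger.info("excluded %d documents lacking %s metadata",
                    excluded, binning)
    bins = sorted(den)
    return TrendSeries(bins=bins,
                       rates=np.array([num.get(b, 0) / den[b] for b in bins]),
                       denominators=np.array([den[b] for b in bins]))


def ailment_rate(assignments: np.ndarray, corpus: Corpus, binning: str,
                 ailment: int) -> TrendSeries:
    """Fraction of each bin's documents assigned to `ailment`.

    `assignments` is the per-document ailment (final-sample a_d), aligned
    with corpus.documents.  Documents lacking the metadata the binning
    needs are excluded from numerator and denominator alike.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != corpus.num_docs:
        raise ValueError("assignments must align with the corpus")
    return _rate_series(corpus, binning,
                        lambda d, doc: assignments[d] == ailment)


def keyword_rate(corpus: Corpus, keyword: str, binning: str) -> TrendSeries:
    """Fraction of each bin's documents containing `keyword` (presence,
    not multiplicity); the keyword is tokenized with the corpus tokenizer."""
    toks = tokenize(keyword)
    if len(toks) != 1:
        raise ValueError("keyword must tokenize to a single token")
    target = toks[0]
    wid = corpus.vocab.get(target)

    def hits(d, doc):
        if wid is None:
            return False
        return any(t.word_id == wid for t in doc.tokens)

    return _rate_series(corpus, binning, hits)


def assign_topic_lda(stats: LDABGStats, d: int) -> int | None:
    """Document d's topic: the topic with the most non-background tokens.

    Ties break to the lowest index; a document with zero non-background
    tokens is unassigned (None) and excluded from rate series.
    """
    if stats.n_doc_top[d] == 0:
        return None
    return int(np.argmax(stats.n_doc_topic[d]))


def _align(series_a, series_b):
    if isinstance(series_a, TrendSeries) and isinstance(series_b, TrendSeries):
        common = [b for b in series_a.bins if b in set(series_b.bins)]
        dropped = (len(series_a.bins) - len(common)) + (len(series_b.bins) - len(common))
        if dropped:
            logger.info("dropped %d bins present in only one series", dropped)
        ia = {b: i for i, b in enumerate(series_a.bins)}
        ib = {b: i for i, b in enumerate(series_b.bins)}
        return (series_a.rates[[ia[b] for b in common]],
                series_b.rates[[ib[b] for b in common]])
    a = series_a.rates if isinstance(series_a, TrendSeries) else np.asarray(series_a, float)
    b = series_b.rates if isinstance(series_b, TrendSeries) else np.asarray(series_b, float)
    if len(a) != len(b):
        raise ValueError("plain arrays must already be aligned")
    return a, b


def pearson(series_a, series_b) -> float:
    """Sample Pearson correlation over the bins common to both series."""
    a, b = _align(series_a, series_b)
    if len(a) < 3:
        raise ValueError("need at least 3 common bins")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a series")
    return float(sstats.pearsonr(a, b).statistic)


def zscore(series):
    """Standardize to mean 0, sample standard deviation 1 (so differently
    scaled series are comparable on one axis)."""
    values = series.rates if isinstance(series, TrendSeries) else np.asarray(series, float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    standardized = (values - values.mean()) / sd
    if isinstance(series, TrendSeries):
        return TrendSeries(bins=list(series.bins), rates=standardized,
                           denominators=series.denominators.copy())
    return standardized


def load_external_series(path: str | Path) -> TrendSeries:
    """Read an external (bin, value) CSV; bins are ISO dates or region codes."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("external series needs (bin, value) columns")
    bins = [str(b) for b in df.iloc[:, 0]]
    order = np.argsort(bins)
    return TrendSeries(bins=[bins[i] for i in order],
                       rates=df.iloc[:, 1].to_numpy(float)[order],
                       denominators=np.ones(len(bins), dtype=np.int64))
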
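"""Informative word priors and model configuration.

Each ailment i carries a Dirichlet prior over its word distributions
decomposed as beta_i = s_i * m_i: the mean m_i is the (smoothed)
empirical unigram distribution of that ailment's reference articles,
and the scalar precision s_i expresses how strongly the model should
trust it.  The mean stays fixed during training; the precision is
optimized by marginal-likelihood updates.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus import Vocabulary, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "AilmentPriorSet",
    "AlphaSet",
    "FixedHypers",
    "ModelConfig",
    "build_prior_means",
    "read_reference_dir",
    "default_config",
]


@dataclasses.dataclass
class AilmentPriorSet:
    """Per-ailment prior mean vectors m_i (rows sum to 1) and precisions s_i."""

    means: np.ndarray       # (A, W) float64, rows normalized
    precisions: np.ndarray  # (A,) float64, > 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.precisions = np.asarray(self.precisions, dtype=np.float64)
        if self.means.ndim != 2:
            raise ValueError("means must be (A, W)")
        if self.precisions.shape != (self.means.shape[0],):
            raise ValueError("precisions must have one entry per ailment")
        if np.any(self.precisions <= 0):
            raise ValueError("precisions must be positive")

    @property
    def num_ailments(self) -> int:
        return self.means.shape[0]

    @classmethod
    def symmetric(cls, num_ailments: int, num_words: int,
                  precision: float = 100.0) -> "AilmentPriorSet":
        means = np.full((num_ailments, num_words), 1.0 / num_words)
        return cls(means=means, precisions=np.full(num_ailments, precision))


@dataclasses.dataclass
class AlphaSet:
    """One alpha_i vector (length Z, entries > 0) per ailment."""

    alpha: np.ndarray  # (A, Z) float64

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if np.any(self.alpha <= 0):
            raise ValueError("alpha entries must be positive")

    @classmethod
    def symmetric(cls, num_ailments: int, num_topics: int,
                  value: float = 1.0) -> "AlphaSet":
        return cls(alpha=np.full((num_ailments, num_topics), value))


@dataclasses.dataclass
class FixedHypers:
    """Hyperparameters held fixed during training.

    beta_flat: symmetric Dirichlet for topic and background word
    distributions.  sigma: symmetric Dirichlet over ailment prevalence.
    gamma: symmetric Beta over the per-document ailment-vs-topic switch.
    lam: probability a token is non-background (1 - lam is the noise rate).
    """

    beta_flat: float = 0.01
    sigma: float = 1.0
    gamma: float = 1.0
    lam: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must lie in [0, 1]")
        if min(self.beta_flat, self.sigma, self.gamma) <= 0:
            raise ValueError("beta_flat, sigma, gamma must be positive")


@dataclasses.dataclass
class ModelConfig:
    """Full training configuration with the defaults used in the study."""

    num_ailments: int = 20
    num_topics: int = 20
    lam: float = 0.2
    gamma: float = 1.0
    sigma: float = 1.0
    beta_flat: float = 0.01
    iterations: int = 8000
    alpha_init: float = 1.0
    s_init: float = 100.0
    smoothing: float = 0.01
    hyperopt_interval: int = 10
    hyperopt_passes: int = 5
    hyperopt_min_group: int = 5
    optimize_hypers: bool = True
    num_increments: int = 10
    checkpoint_every: int = 0
    log_likelihood_every: int = 50
    seed: int = 0

    def fixed_hypers(self) -> FixedHypers:
        return FixedHypers(beta_flat=self.beta_flat, sigma=self.sigma,
                           gamma=self.gamma, lam=self.lam)

    def alpha_set(self) -> AlphaSet:
        return AlphaSet.symmetric(self.num_ailments, self.num_topics,
                                  self.alpha_init)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(data)
        logger.info("config: %s", cfg.to_dict())
        return cfg


def default_config() -> ModelConfig:
    """The study defaults: A = Z = 20, lam = 0.2 (noise probability 0.8),
    gamma = sigma = 1, beta = 0.01 for non-ailment distributions, 8000
    Gibbs iterations."""
    return ModelConfig()


def build_prior_means(
    reference_texts_by_ailment: Sequence[Sequence[str]],
    vocab: Vocabulary,
    smoothing: float = 0.01,
    s_init: float = 100.0,
) -> AilmentPriorSet:
    """Empirical unigram distributions of per-ailment reference texts.

    ``m_i[v] = (count of word v in ailment i's references + smoothing) /
    (total + W * smoothing)``.  Words absent from the reference texts get
    mass ``smoothing / total`` rather than zero, so no tweet word is
    a-priori impossible as an ailment word.  An ailment with no reference
    text at all falls back to the uniform distribution (with a warning).
    Reference-document order does not affect the result.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    num_ailments = len(reference_texts_by_ailment)
    num_words = len(vocab)
    means = np.zeros((num_ailments, num_words))
    for i, texts in enumerate(reference_texts_by_ailment):
        counts = np.zeros(num_words)
        for text in texts:
            for tok in tokenize(text):
                wid = vocab.get(tok)
                if wid is not None:
                    counts[wid] += 1
        total = counts.sum()
        if total == 0 and smoothing == 0:
            logger.warning("ailment %d has no usable reference text; "
                           "using a uniform prior mean", i)
            means[i] = 1.0 / num_words
        else:
            means[i] = (counts + smoothing) / (total + num_words * smoothing)
    return AilmentPriorSet(means=means,
                           precisions=np.full(num_ailments, float(s_init)))


def read_reference_dir(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read per-ailment reference corpora from a directory.

    Each subdirectory (or top-level ``.txt`` file) is one ailment, ordered
    by name; returns (ailment names, list of text lists).
    """
    root = Path(path)
    names: list[str] = []
    texts: list[list[str]] = []
    for entry in sorted(root.iterdir()):
        if entry.is_dir():
            names.append(entry.name)
            texts.append([p.read_text(encoding="utf-8")
                          for p in sorted(entry.glob("*.txt"))])
        elif entry.suffix == ".txt":
            names.append(entry.stem)
            texts.append([entry.read_text(encoding="utf-8")])
    return names, texts
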
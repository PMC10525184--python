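"""Seeded generator of keyword-planted labeled corpora.

Documents are i.i.d. token mixtures: with probability ``keyword_rate`` a
token comes from the document's class-specific keyword set (the sets are
pairwise disjoint), otherwise from a shared noise vocabulary. The exact
keyword positions are recorded so that token-attribution quality can be
scored against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from textcam.preprocess import Document

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 5
    docs_per_class: int = 100
    class_keywords: Optional[tuple[tuple[str, ...], ...]] = None  # auto if None
    keywords_per_class: int = 8
    keyword_rate: float = 0.3
    noise_vocab_size: int = 500
    doc_length: tuple[int, int] = (30, 600)  # inclusive range
    seed: Optional[int] = None

    def resolved_keywords(self) -> tuple[tuple[str, ...], ...]:
        if self.class_keywords is not None:
            return self.class_keywords
        return tuple(
            tuple(f"kw{c}x{i}" for i in range(self.keywords_per_class))
            for c in range(self.n_classes)
        )

    def validate(self) -> None:
        if self.n_classes < 1 or self.docs_per_class < 1:
            raise ValueError("n_classes and docs_per_class must be >= 1")
        if not (0.0 < self.keyword_rate <= 1.0):
            raise ValueError(f"keyword_rate must be in (0, 1], got {self.keyword_rate}")
        if self.noise_vocab_size < 1:
            raise ValueError("noise_vocab_size must be >= 1")
        lo, hi = self.doc_length
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid doc_length range {self.doc_length}")
        kw = self.resolved_keywords()
        if len(kw) != self.n_classes:
            raise ValueError("need one keyword set per class")
        seen: set[str] = set()
        for ks in kw:
            if not ks:
                raise ValueError("keyword sets must be non-empty")
            if seen & set(ks):
                raise ValueError("class keyword sets must be pairwise disjoint")
            seen |= set(ks)


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[Document], dict[str, list[int]]]:
    """Generate ``docs_per_class`` labeled documents per class.

    Returns the documents plus a map from document id to the token positions
    that were drawn from the class keyword set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    keywords = [np.array(ks, dtype=object) for ks in spec.resolved_keywords()]
    noise = np.array([f"n{i}word" for i in range(spec.noise_vocab_size)], dtype=object)
    lo, hi = spec.doc_length
    docs: list[Document] = []
    truth: dict[str, list[int]] = {}
    for c in range(spec.n_classes):
        for d in range(spec.docs_per_class):
            length = int(rng.integers(lo, hi + 1))
            is_kw = rng.random(length) < spec.keyword_rate
            tokens = np.where(
                is_kw,
                rng.choice(keywords[c], size=length),
                rng.choice(noise, size=length),
            )
            doc_id = f"{c}-{d}"
            docs.append(Document(id=doc_id, text=" ".join(tokens.tolist()), label=c))
            truth[doc_id] = np.flatnonzero(is_kw).tolist()
    return docs, truth


def keyword_localization_score(attr, keyword_positions: Sequence[int]) -> float:
    """1.0 if the mean attribution score over keyword cells strictly exceeds
    the mean over non-keyword non-pad cells, else 0.0.

    Raises ``ValueError`` when the comparison is undefined (no keyword
    tokens, or no non-keyword tokens, inside the grid).
    """
    scores = [e.score for e in attr.entries if not e.is_pad]
    n = len(scores)
    kw = {p for p in keyword_positions if p < n}  # positions beyond a truncated grid drop out
    if not kw:
        raise ValueError("document has no keyword tokens inside the grid")
    if len(kw) == n:
        raise ValueError("document has no non-keyword tokens inside the grid")
    arr = np.asarray(scores, dtype=np.float64)
    mask = np.zeros(n, dtype=bool)
    mask[list(kw)] = True
    return 1.0 if arr[mask].mean() > arr[~mask].mean() else 0.0


def corpus_localization_score(
    attrs: Sequence, truths: Sequence[Sequence[int]]
) -> float:
    """Mean per-document localization score; undefined documents are
    excluded (and logged)."""
    if len(attrs) != len(truths):
        raise ValueError("one truth sequence is required per attribution")
    values = []
    for i, (attr, truth) in enumerate(zip(attrs, truths)):
        try:
            values.append(keyword_localization_score(attr, truth))
        except ValueError as exc:
            logger.info("excluding document %d from localization score: %s", i, exc)
    if not values:
        raise ValueError("no document admitted a localization score")
    return float(np.mean(values))
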
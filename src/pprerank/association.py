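"""Sentence-level co-occurrence statistics and mutual-information association.

Association between two identifiers x and y is measured by the un-logged
pointwise mutual information ratio over sentences::

    MI(x, y) = P(x, y) / (P(x) * P(y))

where P(x) is x's sentence frequency divided by N, the number of sentences
containing at least one gene identifier, and P(x, y) is the fraction of
those sentences mentioning both.  Counts are over distinct sentences: a
sentence mentioning x twice still contributes one to sent_count(x).

The association backend is pluggable; MI is the shipped default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, TextIO

from pprerank.corpus_io import Document

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """An unknown association backend was requested."""


def _key(x: str, y: str) -> tuple[str, str]:
    return (x, y) if x <= y else (y, x)


@dataclass
class CooccurrenceStats:
    """Sentence counts backing P(x), P(y) and P(x, y)."""

    n_sentences: int = 0  # sentences containing >=1 gene identifier
    sent_count: dict[str, int] = field(default_factory=dict)
    pair_count: dict[tuple[str, str], int] = field(default_factory=dict)

    def pair(self, x: str, y: str) -> int:
        return self.pair_count.get(_key(x, y), 0)

    def validate(self) -> None:
        for (x, y), c in self.pair_count.items():
            if c > min(self.sent_count.get(x, 0), self.sent_count.get(y, 0)):
                raise ValueError(f"pair_count({x},{y})={c} exceeds a marginal")
        if self.sent_count and max(self.sent_count.values()) > self.n_sentences:
            raise ValueError("sent_count exceeds N")


def build_cooccurrence_stats(doc: Document) -> CooccurrenceStats:
    """Count identifier sentence occurrences and co-occurrences in ``doc``."""
    per_sentence: list[set[str]] = [set() for _ in doc.sentences]
    for m in doc.mentions:
        idx = doc.sentence_of(m)
        if idx is None:
            logger.debug("mention outside any sentence: %s", m)
            continue
        per_sentence[idx].add(m.identifier)
    stats = CooccurrenceStats()
    for ids in per_sentence:
        if not ids:
            continue
        stats.n_sentences += 1
        for x in ids:
            stats.sent_count[x] = stats.sent_count.get(x, 0) + 1
        ordered = sorted(ids)
        for i, x in enumerate(ordered):
            for y in ordered[i + 1 :]:
                k = (x, y)
                stats.pair_count[k] = stats.pair_count.get(k, 0) + 1
    return stats


def mutual_information(stats: CooccurrenceStats, x: str, y: str) -> float:
    """MI(x,y) = N * c(x,y) / (c(x) * c(y)); 0 for unseen or disjoint pairs."""
    cx = stats.sent_count.get(x, 0)
    cy = stats.sent_count.get(y, 0)
    cxy = stats.pair(x, y)
    if stats.n_sentences == 0 or cxy == 0:
        return 0.0
    if cx == 0 or cy == 0:
        logger.debug("identifier absent from sentence stats: %s / %s", x, y)
        return 0.0
    return stats.n_sentences * cxy / (cx * cy)


#: Registered association backends, each ``f(stats, x, y) -> float``.
ASSOCIATION_BACKENDS: dict[str, Callable[[CooccurrenceStats, str, str], float]] = {
    "mi": mutual_information,
}


def association(stats: CooccurrenceStats, x: str, y: str, backend: str = "mi") -> float:
    try:
        fn = ASSOCIATION_BACKENDS[backend]
    except KeyError:
        raise ConfigurationError(
            f"unknown association backend {backend!r}; known: {sorted(ASSOCIATION_BACKENDS)}"
        ) from None
    return fn(stats, x, y)


def make_associator(stats: CooccurrenceStats, backend: str = "mi") -> Callable[[str, str], float]:
    """Bind stats and backend into a two-argument association function."""
    if backend not in ASSOCIATION_BACKENDS:
        raise ConfigurationError(
            f"unknown association backend {backend!r}; known: {sorted(ASSOCIATION_BACKENDS)}"
        )
    fn = ASSOCIATION_BACKENDS[backend]
    return lambda x, y: fn(stats, x, y)


# ---------------------------------------------------------------------------
# TSV export / import


def write_stats(stats: CooccurrenceStats, singles: TextIO, pairs: TextIO) -> None:
    singles.write(f"# N={stats.n_sentences}\n")
    for ident in sorted(stats.sent_count):
        singles.write(f"{ident}\t{stats.sent_count[ident]}\n")
    pairs.write(f"# N={stats.n_sentences}\n")
    for (a, b) in sorted(stats.pair_count):
        pairs.write(f"{a}\t{b}\t{stats.pair_count[(a, b)]}\n")


def read_stats(singles: TextIO, pairs: TextIO) -> CooccurrenceStats:
    stats = CooccurrenceStats()
    for line in singles:
        line = line.rstrip("\n")
        if line.startswith("# N="):
            stats.n_sentences = int(line[4:])
        elif line:
            ident, count = line.split("\t")
            stats.sent_count[ident] = int(count)
    for line in pairs:
        line = line.rstrip("\n")
        if line.startswith("#") or not line:
            continue
        a, b, count = line.split("\t")
        stats.pair_count[_key(a, b)] = int(count)
    stats.validate()
    return stats
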
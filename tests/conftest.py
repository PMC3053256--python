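"""Shared fixtures: worked-example data and document construction helpers."""

from __future__ import annotations

import random
import re

import pytest

from pprerank.association import CooccurrenceStats, make_associator
from pprerank.corpus_io import (
    AnnotationRecord,
    Block,
    BlockType,
    Document,
    attach_annotations,
    derive_keyword_terms,
    segment_sentences,
)
from pprerank.ranking import AccuracyProfile, RankedList
from pprerank.rerank import CandidateList, CandidateListSet, generate_candidate_lists

_ACCESSION_RE = re.compile(r"\b[OPQ][0-9][A-Z0-9]{3}[0-9]\b")


def build_doc(
    spec: list[tuple[BlockType, tuple[str, ...], str]], article_id: str = "doc"
) -> Document:
    """Build a Document from (block_type, heading_path, text) triples.

    Every accession-shaped token (``P12345``) in the text is automatically
    attached as a mention of itself, and sentences are segmented.
    """
    blocks = [
        Block(btype, heading, text, idx) for idx, (btype, heading, text) in enumerate(spec)
    ]
    doc = Document(article_id=article_id, blocks=blocks,
                   keyword_terms=derive_keyword_terms(blocks))
    segment_sentences(doc)
    records = [
        AnnotationRecord(article_id, b.index, m.start(), m.end(), m.group(0), m.group(0))
        for b in blocks
        for m in _ACCESSION_RE.finditer(b.text)
    ]
    attach_annotations(doc, records)
    return doc


def stats_from_sentences(sentences: list[set[str]]) -> CooccurrenceStats:
    """Independent distinct-sentence counting oracle for co-occurrence stats."""
    stats = CooccurrenceStats()
    for ids in sentences:
        if not ids:
            continue
        stats.n_sentences += 1
        for x in ids:
            stats.sent_count[x] = stats.sent_count.get(x, 0) + 1
        ordered = sorted(ids)
        for i, x in enumerate(ordered):
            for y in ordered[i + 1 :]:
                stats.pair_count[(x, y)] = stats.pair_count.get((x, y), 0) + 1
    return stats


# ---------------------------------------------------------------------------
# The published four-identifier worked example.  Sentence counts are chosen
# to be consistent with every printed ordering (article mention counts and
# sentence counts differ; only the orderings are pinned down).

WORKED_IDS = ["P40337", "P40338", "Q05513", "Q9NPB6"]


@pytest.fixture
def worked_stats() -> CooccurrenceStats:
    stats = CooccurrenceStats(
        n_sentences=30,
        sent_count={"P40337": 20, "P40338": 6, "Q05513": 8, "Q9NPB6": 5},
        pair_count={
            ("P40337", "P40338"): 1,
            ("P40337", "Q05513"): 2,
            ("P40337", "Q9NPB6"): 2,
            ("Q05513", "Q9NPB6"): 1,
        },
    )
    stats.validate()
    return stats


@pytest.fixture
def worked_ranking() -> RankedList:
    return RankedList("worked", list(WORKED_IDS))


@pytest.fixture
def worked_lists(worked_stats, worked_ranking) -> CandidateListSet:
    return generate_candidate_lists(worked_ranking, make_associator(worked_stats))


@pytest.fixture
def decider_example() -> CandidateListSet:
    """L = {l_w = [w, x, y, z], l_x = [_, x, y, w]} from the printed example."""
    return CandidateListSet(
        lists={
            "w": CandidateList("w", 1, ["w", "x", "y", "z"]),
            "x": CandidateList("x", 2, [None, "x", "y", "w"]),
        }
    )


# ---------------------------------------------------------------------------
# Random re-ranking instances for DP-vs-oracle properties


def make_random_instance(
    rng: random.Random, min_ids: int = 2, max_ids: int = 6
) -> tuple[RankedList, CandidateListSet, AccuracyProfile]:
    n = rng.randint(min_ids, max_ids)
    ids = [f"G{k}" for k in range(n)]
    assoc_table: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                assoc_table[frozenset((ids[i], ids[j]))] = rng.uniform(0.1, 5.0)
    r = RankedList("rand", ids)
    L = generate_candidate_lists(
        r, lambda x, y: assoc_table.get(frozenset((x, y)), 0.0)
    )
    acc = {}
    value = rng.uniform(0.6, 1.0)
    for i in range(1, n + 1):
        acc[i] = max(value, 1e-3)
        value *= rng.uniform(0.5, 1.0)
    profile = AccuracyProfile(acc=acc)
    return r, L, profile


@pytest.fixture
def random_instance_factory():
    return make_random_instance
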
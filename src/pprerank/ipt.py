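"""Interaction-pair extraction and ranking.

Two identifiers described in the same sentence form a candidate interaction
pair.  A pair (x at rank i, y at rank j) is scored by

    IPTScore(x, i, y, j) = MI(x, y) * interactor_score(x, i) * interactor_score(y, j)

where the interactor score defaults to the re-ranking ``score`` at the
pair members' final ranks.  Two ablation modes are shipped: ``mi`` ranks
pairs by association alone, and ``mi_svm_accuracy`` replaces the score
function with the per-rank accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TextIO

from pprerank.association import CooccurrenceStats, mutual_information
from pprerank.ranking import AccuracyProfile, RankedList
from pprerank.rerank import CandidateListSet, RerankedList, score

logger = logging.getLogger(__name__)

IPT_MODES = ("mi", "mi_svm_accuracy", "mi_rerank")


@dataclass
class ScoredPair:
    id_a: str
    id_b: str
    mi: float
    score_a: float
    score_b: float
    ipt_score: float
    rank_a: int = 0
    rank_b: int = 0


def candidate_pairs(stats: CooccurrenceStats) -> list[tuple[str, str]]:
    """All unordered identifier pairs co-occurring in >=1 sentence."""
    return sorted(
        (a, b) for (a, b), c in stats.pair_count.items() if c >= 1 and a != b
    )


def _interactor_score(
    x: str,
    i: int,
    L: CandidateListSet,
    profile: AccuracyProfile,
    mode: str,
    floor_epsilon: float,
    include_own: bool,
) -> float:
    if mode == "mi":
        return 1.0
    if mode == "mi_svm_accuracy":
        return profile.lookup(i)
    s = score(x, i, L, profile, include_own=include_own)
    # Appended-tail identifiers score 0 at their final rank; a floor keeps
    # MI ordering information for such pairs instead of collapsing them.
    return s if s > 0.0 else floor_epsilon


def ipt_score(
    x: str,
    i: int,
    y: str,
    j: int,
    stats: CooccurrenceStats,
    L: CandidateListSet,
    profile: AccuracyProfile,
    mode: str = "mi_rerank",
    floor_epsilon: float = 1e-6,
    include_own: bool = True,
) -> float:
    """MI(x,y) times the two interactor scores; symmetric in (x,i) and (y,j)."""
    mi = mutual_information(stats, x, y)
    if mi == 0.0:
        return 0.0
    sx = _interactor_score(x, i, L, profile, mode, floor_epsilon, include_own)
    sy = _interactor_score(y, j, L, profile, mode, floor_epsilon, include_own)
    return mi * sx * sy


def rank_pairs(
    reranked: RerankedList,
    stats: CooccurrenceStats,
    L: CandidateListSet,
    profile: AccuracyProfile,
    mode: str = "mi_rerank",
    rank_mode: str = "reranked",
    svm_ranking: RankedList | None = None,
    floor_epsilon: float = 1e-6,
    include_own: bool = True,
) -> list[ScoredPair]:
    """Score and sort all co-occurring pairs.

    ``rank_mode='reranked'`` takes i, j from the re-ranked list (default);
    ``'svm'`` takes them from the supplied initial ranking instead.
    """
    if mode not in IPT_MODES:
        raise ValueError(f"unknown IPT mode {mode!r}; known: {IPT_MODES}")
    if rank_mode == "reranked":
        positions = {x: k + 1 for k, x in enumerate(reranked.identifiers)}
    elif rank_mode == "svm":
        if svm_ranking is None:
            raise ValueError("rank_mode='svm' requires svm_ranking")
        positions = {x: k + 1 for k, x in enumerate(svm_ranking.identifiers)}
    else:
        raise ValueError(f"unknown rank mode {rank_mode!r}")

    pairs: list[ScoredPair] = []
    for a, b in candidate_pairs(stats):
        if a not in positions or b not in positions:
            logger.debug("pair (%s, %s) outside the ranked list; skipped", a, b)
            continue
        i, j = positions[a], positions[b]
        mi = mutual_information(stats, a, b)
        sa = _interactor_score(a, i, L, profile, mode, floor_epsilon, include_own)
        sb = _interactor_score(b, j, L, profile, mode, floor_epsilon, include_own)
        pairs.append(
            ScoredPair(a, b, mi=mi, score_a=sa, score_b=sb, ipt_score=mi * sa * sb,
                       rank_a=i, rank_b=j)
        )
    pairs.sort(
        key=lambda p: (-p.ipt_score, -p.mi, p.rank_a + p.rank_b, (p.id_a, p.id_b))
    )
    return pairs


def write_pairs(article_id: str, pairs: list[ScoredPair], stream: TextIO) -> None:
    stream.write("article_id\trank\tid_a\tid_b\tipt_score\tmi\n")
    for k, p in enumerate(pairs, start=1):
        stream.write(
            f"{article_id}\t{k}\t{p.id_a}\t{p.id_b}\t{p.ipt_score!r}\t{p.mi!r}\n"
        )
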
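"""Co-occurrence-driven re-ranking of an interactor ranked list.

Given the initial ranked list r, each identifier x at rank i proposes a
candidate list l_x: slots 1..i-1 empty, x at slot i, and the identifiers
co-occurring with x filling the following slots in descending association
order (overflow beyond |r| is dropped).  A re-ranked list is scored rank by
rank with

    score(x, i, L) = rankN_Ratio(x, i, L)
                     * svmAccuracy(i)
                     * svmAccuracy(deciderRank(x, i, L))

and the overall score of a full list is the product of its per-rank scores.
A legal list holds each identifier at most once; a dynamic program finds
the best list under that constraint by keeping, for every candidate at
every rank, the best predecessor whose traced back-chain does not already
contain the candidate.  The DP follows the published pseudo-code exactly,
including its single-chain duplicate check, which makes it a heuristic
relative to the exhaustive optimum; :func:`brute_force_rerank` provides
that optimum on small instances so the gap can be measured.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator

from pprerank.ranking import AccuracyProfile, RankedList

logger = logging.getLogger(__name__)

Assoc = Callable[[str, str], float]


@dataclass
class CandidateList:
    """The partial ranked list l_x proposed by identifier x at rank i.

    ``slots`` has length |r|; index k (0-based) is rank k+1.  Empty slots
    are None.
    """

    owner: str
    owner_rank: int  # 1-based rank of owner in r
    slots: list[str | None]

    def slot(self, rank: int) -> str | None:
        """1-based slot accessor."""
        return self.slots[rank - 1]


@dataclass
class CandidateListSet:
    """The set L = {l_x | x in r}, keyed by owner identifier."""

    lists: dict[str, CandidateList] = field(default_factory=dict)

    def __iter__(self) -> Iterator[CandidateList]:
        return iter(self.lists.values())

    def __getitem__(self, owner: str) -> CandidateList:
        return self.lists[owner]

    def __len__(self) -> int:
        return len(self.lists)


@dataclass
class ScoreTuple:
    id: str
    score: float
    overallscore: float
    from_id: str | None
    chain: frozenset[str] = frozenset()  # ids on this tuple's traced path


@dataclass
class RerankedList:
    article_id: str
    identifiers: list[str]
    overall_score: float
    appended_tail: list[str] = field(default_factory=list)


def new_ranked_list(x: str, i: int, r: RankedList, assoc: Assoc) -> CandidateList:
    """Build l_x: x at slot i, co-occurring identifiers after it in
    descending association order; overflow past |r| dropped."""
    n = len(r)
    if not (1 <= i <= n) or r.identifiers[i - 1] != x:
        raise ValueError(f"{x!r} is not the rank-{i} identifier of r")
    rank_in_r = {ident: k + 1 for k, ident in enumerate(r.identifiers)}
    cooc = [(y, assoc(x, y)) for y in r.identifiers if y != x]
    cooc = [(y, a) for y, a in cooc if a > 0]
    cooc.sort(key=lambda ya: (-ya[1], rank_in_r[ya[0]], ya[0]))
    slots: list[str | None] = [None] * n
    slots[i - 1] = x
    for k, (y, _) in enumerate(cooc):
        pos = i + k  # 0-based index of rank i+1+k... slot i+1 is index i
        if pos >= n:
            break
        slots[pos] = y
    return CandidateList(owner=x, owner_rank=i, slots=slots)


def generate_candidate_lists(r: RankedList, assoc: Assoc) -> CandidateListSet:
    return CandidateListSet(
        lists={
            x: new_ranked_list(x, i + 1, r, assoc)
            for i, x in enumerate(r.identifiers)
        }
    )


def is_rank_n(x: str, i: int, l: CandidateList) -> int:
    """1 iff slot i of l holds x."""
    return 1 if l.slot(i) == x else 0


def rank_n_ratio(x: str, i: int, L: CandidateListSet, include_own: bool = True) -> float:
    """Fraction of x's placements across all candidate lists that are at rank i.

    ``include_own=True`` (default) counts x's own list l_x in both sums;
    the literal published formula restricts to lists owned by y != x, which
    leaves isolated identifiers with an undefined 0/0 ratio — that mode
    returns 0 and logs.
    """
    num = 0
    den = 0
    for l in L:
        if not include_own and l.owner == x:
            continue
        for j, slot in enumerate(l.slots, start=1):
            if slot == x:
                den += 1
                if j == i:
                    num += 1
    if den == 0:
        logger.debug("rankN_Ratio(%s, %d): no counted placements", x, i)
        return 0.0
    return num / den


def decider_rank(x: str, i: int, L: CandidateListSet) -> int:
    """Best (minimum) original rank among the owners whose list places x at
    rank i; equals i when only x's own list does."""
    supporters = [l.owner_rank for l in L if is_rank_n(x, i, l)]
    if not supporters:
        raise ValueError(f"no candidate list places {x!r} at rank {i}")
    return min(supporters)


def score(
    x: str,
    i: int,
    L: CandidateListSet,
    profile: AccuracyProfile,
    placed: frozenset[str] | set[str] = frozenset(),
    include_own: bool = True,
) -> float:
    """Likelihood of x at re-rank i; 0 if x was already placed earlier."""
    if x in placed:
        return 0.0
    ratio = rank_n_ratio(x, i, L, include_own=include_own)
    if ratio == 0.0:
        return 0.0
    return ratio * profile.lookup(i) * profile.lookup(decider_rank(x, i, L))


# ---------------------------------------------------------------------------
# Dynamic program


def _candidates_by_rank(r: RankedList, L: CandidateListSet) -> dict[int, list[str]]:
    rank_in_r = {ident: k + 1 for k, ident in enumerate(r.identifiers)}
    out: dict[int, list[str]] = {}
    for i in range(1, len(r) + 1):
        ids = {l.slot(i) for l in L if l.slot(i) is not None}
        out[i] = sorted(ids, key=lambda x: (rank_in_r.get(x, 1 << 30), x))
    return out


def build_score_info(
    r: RankedList,
    L: CandidateListSet,
    profile: AccuracyProfile,
    include_own: bool = True,
) -> dict[int, list[ScoreTuple]]:
    """Forward DP fill: rank -> [(id, score, overallscore, from)].

    A candidate at rank i may extend predecessor tuple t at rank i-1 only
    if its identifier is absent from t's traced from-chain; its overall
    score is its own score times the best admissible predecessor's.
    """
    n = len(r)
    rank_in_r = {ident: k + 1 for k, ident in enumerate(r.identifiers)}
    candidates = _candidates_by_rank(r, L)
    info: dict[int, list[ScoreTuple]] = {}
    info[1] = [
        ScoreTuple(
            id=x,
            score=(s := score(x, 1, L, profile, include_own=include_own)),
            overallscore=s,
            from_id=None,
            chain=frozenset({x}),
        )
        for x in candidates[1]
    ]
    for i in range(2, n + 1):
        row: list[ScoreTuple] = []
        for x in candidates[i]:
            s = score(x, i, L, profile, include_own=include_own)
            admissible = [t for t in info[i - 1] if x not in t.chain]
            if not admissible:
                row.append(ScoreTuple(x, s, 0.0, None, frozenset({x})))
                continue
            best = min(
                admissible,
                key=lambda t: (-t.overallscore, -t.score, rank_in_r.get(t.id, 1 << 30), t.id),
            )
            row.append(
                ScoreTuple(x, s, s * best.overallscore, best.id, best.chain | {x})
            )
        info[i] = row
    return info


def find_optimal_reranking(
    r: RankedList,
    L: CandidateListSet,
    profile: AccuracyProfile,
    include_own: bool = True,
) -> RerankedList:
    """DP re-ranking: forward fill, then backward trace from the best tuple
    at the last rank.  Identifiers of r absent from the traced path are
    appended in r-order; if every final tuple scores 0, r is returned
    unchanged with a warning."""
    n = len(r)
    if n == 0:
        return RerankedList(r.article_id, [], 0.0)
    rank_in_r = {ident: k + 1 for k, ident in enumerate(r.identifiers)}
    info = build_score_info(r, L, profile, include_own=include_own)
    last = info[n]
    best = min(
        last, key=lambda t: (-t.overallscore, -t.score, rank_in_r.get(t.id, 1 << 30), t.id)
    )
    if best.overallscore <= 0.0:
        logger.warning(
            "re-ranking of %s degenerate (all final overall scores 0); keeping r",
            r.article_id,
        )
        return RerankedList(r.article_id, list(r.identifiers), 0.0)
    path: list[str] = []
    t: ScoreTuple | None = best
    i = n
    while t is not None:
        path.append(t.id)
        if t.from_id is None:
            break
        i -= 1
        t = next(u for u in info[i] if u.id == t.from_id)
    path.reverse()
    tail = [x for x in r.identifiers if x not in path]
    return RerankedList(
        r.article_id, path + tail, overall_score=best.overallscore, appended_tail=tail
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle


def brute_force_rerank(
    r: RankedList,
    L: CandidateListSet,
    profile: AccuracyProfile,
    include_own: bool = True,
    guard: int = 8,
) -> RerankedList:
    """Enumerate every duplicate-free assignment of one rank-i candidate per
    rank and return the product-score optimum.  Guarded against blow-up."""
    n = len(r)
    if n > guard:
        raise ValueError(f"brute force refused: |r|={n} exceeds guard bound {guard}")
    if n == 0:
        return RerankedList(r.article_id, [], 0.0)
    rank_in_r = {ident: k + 1 for k, ident in enumerate(r.identifiers)}
    candidates = _candidates_by_rank(r, L)
    score_table = {
        (x, i): score(x, i, L, profile, include_own=include_own)
        for i in candidates
        for x in candidates[i]
    }
    best_ids: tuple[str, ...] | None = None
    best_key: tuple | None = None
    for combo in itertools.product(*(candidates[i] for i in range(1, n + 1))):
        if len(set(combo)) != n:
            continue
        total = 1.0
        for i, x in enumerate(combo, start=1):
            total *= score_table[(x, i)]
        key = (
            -total,
            tuple(rank_in_r.get(x, 1 << 30) for x in combo),
            combo,
        )
        if best_key is None or key < best_key:
            best_key = key
            best_ids = combo
    assert best_ids is not None  # r itself is always an admissible combo
    overall = -best_key[0]
    if overall <= 0.0:
        return RerankedList(r.article_id, list(r.identifiers), 0.0)
    return RerankedList(r.article_id, list(best_ids), overall_score=overall)


# ---------------------------------------------------------------------------
# Output


def write_reranked(results: list[RerankedList], stream) -> None:
    stream.write("article_id\trank\tidentifier\toverall_score\n")
    for res in results:
        for i, ident in enumerate(res.identifiers, start=1):
            stream.write(f"{res.article_id}\t{i}\t{ident}\t{res.overall_score!r}\n")
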
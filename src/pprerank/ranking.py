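"""Initial interactor ranking: features, the Freq baseline, rank accuracies.

The initial ranked list r orders an article's normalized identifiers by
their likelihood of being curatable interactors.  Any scoring model
satisfying the contract ``score(FeatureVector) -> float`` can drive the
ranking; a frequency baseline (with Results-section and earliest-mention
tie-breaks) and an optional max-margin linear model are shipped.

Per-rank accuracies — the fraction of articles whose rank-i identifier is
truly an interactor — feed the re-ranking score as ``svmAccuracy(i)``.
They decrease with rank in practice: top ranks of a trained ranker are more
reliable, and the re-ranker exploits exactly that.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields
from typing import Callable, Iterable, Sequence, TextIO

from pprerank.corpus_io import Block, BlockType, Document

logger = logging.getLogger(__name__)

DEFAULT_INDICATOR_PHRASES = (
    "the aim of this",
    "the purpose of this",
    "we conclude",
    "we propose",
)

_FIGURE_REF_RE = re.compile(r"\bfig(?:ure)?s?\.?\s*\d", re.IGNORECASE)


@dataclass
class FeatureVector:
    """Per-identifier, per-article features for interactor ranking."""

    freq_total: int = 0
    freq_results_ratio: float = 0.0
    in_title: bool = False
    in_abstract: bool = False
    in_first_section: bool = False
    in_results: bool = False
    in_last_section: bool = False
    in_appendix: bool = False
    in_other_section: bool = False
    in_section_heading: bool = False
    in_figure_table_caption: bool = False
    in_keyword_field: bool = False
    in_fullname_field: bool = False
    in_abbrev_field: bool = False
    cooccur_keyword: bool = False
    cooccur_fullname_abbrev: bool = False
    cooccur_figure_reference: bool = False
    indicator_phrase: bool = False

    def as_array(self) -> list[float]:
        return [float(getattr(self, f.name)) for f in fields(self)]


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in fields(FeatureVector))


@dataclass
class RankedList:
    article_id: str
    identifiers: list[str]
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.identifiers)) != len(self.identifiers):
            raise ValueError("ranked list contains duplicate identifiers")

    def rank_of(self, identifier: str) -> int:
        """1-based rank."""
        return self.identifiers.index(identifier) + 1

    def __len__(self) -> int:
        return len(self.identifiers)


@dataclass
class AccuracyProfile:
    """Per-rank accuracy table with floor and clamp policy.

    Lookups beyond the last defined rank clamp to the last value; every
    stored accuracy is floored at ``floor_epsilon`` so that the
    multiplicative re-ranking score never annihilates a candidate outright.
    """

    acc: dict[int, float]
    floor_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not self.acc:
            raise ValueError("accuracy profile must define at least one rank")
        self.acc = {
            i: max(min(v, 1.0), self.floor_epsilon) for i, v in sorted(self.acc.items())
        }
        self._max_rank = max(self.acc)

    @classmethod
    def constant(cls, value: float = 1.0) -> "AccuracyProfile":
        return cls(acc={1: value})

    def lookup(self, rank: int) -> float:
        rank = min(rank, self._max_rank)
        if rank not in self.acc:
            # clamp to nearest defined rank below, else the first
            defined = [i for i in self.acc if i <= rank]
            rank = max(defined) if defined else min(self.acc)
        return self.acc[rank]

    __call__ = lookup


# ---------------------------------------------------------------------------
# Section geography of BODY blocks


def _top_heading(block: Block) -> str:
    return block.heading_path[0] if block.heading_path else ""


def _body_sections(doc: Document) -> dict[int, set[str]]:
    """Map BODY block index -> labels in {first, results, last, appendix, other}."""
    body = [b for b in doc.blocks if b.block_type is BlockType.BODY]
    labels: dict[int, set[str]] = {}
    if not body:
        return labels
    headings: list[str] = []
    for b in body:
        h = _top_heading(b)
        if h not in headings:
            headings.append(h)
    first, last = headings[0], headings[-1]
    for b in body:
        h = _top_heading(b)
        lab: set[str] = set()
        if h == first:
            lab.add("first")
        if h == last:
            lab.add("last")
        if "result" in h.lower():
            lab.add("results")
        if "appendix" in h.lower():
            lab.add("appendix")
        if not lab:
            lab.add("other")
        labels[b.index] = lab
    return labels


def extract_features(
    doc: Document,
    identifier: str,
    indicator_phrases: Sequence[str] = DEFAULT_INDICATOR_PHRASES,
) -> FeatureVector:
    """Deterministic feature vector for one identifier in one article."""
    mentions = [m for m in doc.mentions if m.identifier == identifier]
    if not mentions:
        raise ValueError(f"identifier {identifier!r} has no mentions in {doc.article_id!r}")
    fv = FeatureVector(freq_total=len(mentions))
    sections = _body_sections(doc)
    results_mentions = 0
    surfaces = {m.surface for m in mentions}
    keyword_low = [k.lower() for k in doc.keyword_terms]
    fullnames_low = [full.lower() for full, _ in doc.abbrev_defs]
    abbrevs_low = [abbr.lower() for _, abbr in doc.abbrev_defs]
    phrases_low = [p.lower() for p in indicator_phrases]

    for m in mentions:
        btype = doc.blocks[m.block_index].block_type
        if btype is BlockType.TITLE:
            fv.in_title = True
        elif btype is BlockType.ABSTRACT:
            fv.in_abstract = True
        elif btype in (BlockType.FIGURE, BlockType.TABLE):
            fv.in_figure_table_caption = True
        elif btype is BlockType.BODY:
            lab = sections.get(m.block_index, set())
            fv.in_first_section |= "first" in lab
            fv.in_last_section |= "last" in lab
            fv.in_appendix |= "appendix" in lab
            fv.in_other_section |= "other" in lab
            if "results" in lab:
                fv.in_results = True
                results_mentions += 1
        sidx = doc.sentence_of(m)
        if sidx is not None:
            sent = doc.sentence_text(doc.sentences[sidx]).lower()
            fv.cooccur_keyword |= any(k in sent for k in keyword_low)
            fv.cooccur_fullname_abbrev |= any(
                t in sent for t in fullnames_low + abbrevs_low
            )
            fv.cooccur_figure_reference |= bool(_FIGURE_REF_RE.search(sent))
            fv.indicator_phrase |= any(p in sent for p in phrases_low)
    fv.freq_results_ratio = results_mentions / len(mentions)

    surfaces_low = {s.lower() for s in surfaces} | {identifier.lower()}
    fv.in_section_heading = any(
        s in h.lower() for b in doc.blocks for h in b.heading_path for s in surfaces_low
    )
    fv.in_keyword_field = any(s in keyword_low for s in surfaces_low)
    fv.in_fullname_field = any(s in fullnames_low for s in surfaces_low)
    fv.in_abbrev_field = any(s in abbrevs_low for s in surfaces_low)
    return fv


# ---------------------------------------------------------------------------
# Rankers


def _freq_sort_key(doc: Document) -> Callable[[str], tuple]:
    counts: dict[str, int] = {}
    results_counts: dict[str, int] = {}
    first_pos: dict[str, tuple[int, int]] = {}
    sections = _body_sections(doc)
    for m in sorted(doc.mentions, key=lambda m: (m.block_index, m.start)):
        counts[m.identifier] = counts.get(m.identifier, 0) + 1
        if "results" in sections.get(m.block_index, set()):
            results_counts[m.identifier] = results_counts.get(m.identifier, 0) + 1
        first_pos.setdefault(m.identifier, (m.block_index, m.start))

    def key(ident: str) -> tuple:
        return (
            -counts.get(ident, 0),
            -results_counts.get(ident, 0),
            first_pos.get(ident, (1 << 30, 0)),
            ident,
        )

    return key


def rank_frequency_baseline(doc: Document) -> RankedList:
    """Rank identifiers by article frequency; ties by Results-section
    frequency, then by earliest mention position."""
    key = _freq_sort_key(doc)
    idents = sorted(doc.identifiers(), key=key)
    return RankedList(doc.article_id, idents)


def rank_with_model(
    model,
    features: dict[str, FeatureVector],
    article_id: str = "",
    baseline: RankedList | None = None,
) -> RankedList:
    """Rank by model score descending; ties fall back to baseline order.

    ``model`` is anything exposing ``score(FeatureVector) -> float`` or a
    plain callable.
    """
    scorer = model.score if hasattr(model, "score") else model
    scores: dict[str, float] = {}
    for ident, fv in features.items():
        try:
            scores[ident] = float(scorer(fv))
        except Exception as exc:
            raise RuntimeError(f"model failed scoring identifier {ident!r}") from exc
    base_order = (
        {ident: i for i, ident in enumerate(baseline.identifiers)} if baseline else {}
    )
    idents = sorted(
        features,
        key=lambda x: (-scores[x], base_order.get(x, 1 << 30), -features[x].freq_total, x),
    )
    return RankedList(article_id, idents, scores=scores)


class FreqScoreModel:
    """Trivial scoring backend: score equals total mention frequency."""

    def score(self, fv: FeatureVector) -> float:
        return float(fv.freq_total)


class LinearSvmModel:
    """Max-margin linear reference model over the feature vector.

    A thin wrapper around scikit-learn's LinearSVC; the decision-function
    margin is the ranking score.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self._clf = None

    def fit(self, examples: Iterable[tuple[FeatureVector, bool]]) -> "LinearSvmModel":
        from sklearn.svm import LinearSVC

        X = [fv.as_array() for fv, _ in examples]
        y = [int(label) for _, label in examples]
        self._clf = LinearSVC(C=self.C).fit(X, y)
        return self

    def score(self, fv: FeatureVector) -> float:
        if self._clf is None:
            raise RuntimeError("model not fitted")
        return float(self._clf.decision_function([fv.as_array()])[0])


# ---------------------------------------------------------------------------
# Per-rank accuracy estimation


def estimate_rank_accuracy(
    results: Sequence[tuple[RankedList, set[str]]],
    floor_epsilon: float = 1e-6,
) -> AccuracyProfile:
    """acc[i] = (# articles whose rank-i identifier is gold) /
    (# articles having a rank-i identifier)."""
    if not results:
        raise ValueError("estimate_rank_accuracy needs at least one ranked result")
    max_len = max(len(rl) for rl, _ in results)
    if max_len == 0:
        raise ValueError("all ranked lists are empty")
    acc: dict[int, float] = {}
    for i in range(1, max_len + 1):
        have = [(rl, gold) for rl, gold in results if len(rl) >= i]
        correct = sum(1 for rl, gold in have if rl.identifiers[i - 1] in gold)
        acc[i] = correct / len(have)
    return AccuracyProfile(acc=acc, floor_epsilon=floor_epsilon)


def write_profile(profile: AccuracyProfile, stream: TextIO) -> None:
    stream.write(f"# floor_epsilon={profile.floor_epsilon!r}\n")
    stream.write("rank\taccuracy\n")
    for i, v in sorted(profile.acc.items()):
        stream.write(f"{i}\t{v!r}\n")


def read_profile(stream: TextIO | Iterable[str]) -> AccuracyProfile:
    floor = 1e-6
    acc: dict[int, float] = {}
    for line in stream:
        line = line.rstrip("\n")
        if line.startswith("# floor_epsilon="):
            floor = float(line.split("=", 1)[1])
        elif line and not line.startswith(("#", "rank\t")):
            rank, value = line.split("\t")
            acc[int(rank)] = float(value)
    return AccuracyProfile(acc=acc, floor_epsilon=floor)


def write_feature_matrix(
    rows: Iterable[tuple[str, str, FeatureVector]], stream: TextIO
) -> None:
    stream.write("article_id\tidentifier\t" + "\t".join(FEATURE_NAMES) + "\n")
    for article_id, ident, fv in rows:
        values = "\t".join(repr(v) for v in fv.as_array())
        stream.write(f"{article_id}\t{ident}\t{values}\n")
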
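"""Readers, writers and text normalization for block-structured articles.

Full-text articles are modelled as a flat sequence of typed blocks
(TITLE, ABSTRACT, BODY, FIGURE, KEYWORD, TABLE), each carrying its own text
and a heading path (section, sub-section).  Gene-mention annotations are
standoff: character spans relative to a block's text, mapped to database
identifiers.  Gene normalization itself is upstream of this package — its
output is an input here.

Canonical on-disk dialect: exactly two lines per block, UTF-8 —

    TYPE<TAB>text content on one line
    heading | path | joined | by " | " (may be empty)

A lossless JSON form mirroring :class:`Document` is also provided.
Coordinates are 0-based half-open character offsets, per block.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence, TextIO

logger = logging.getLogger(__name__)

HEADING_DELIMITER = " | "

#: Abbreviations that never terminate a sentence.
DEFAULT_ABBREVIATIONS = ("Fig.", "Figs.", "et al.", "e.g.", "i.e.", "vs.", "cf.", "ca.")


class ParseError(ValueError):
    """A block file violates the two-line-per-block dialect."""


class BlockType(str, Enum):
    TITLE = "TITLE"
    ABSTRACT = "ABSTRACT"
    BODY = "BODY"
    FIGURE = "FIGURE"
    KEYWORD = "KEYWORD"
    TABLE = "TABLE"


@dataclass
class Block:
    block_type: BlockType
    heading_path: tuple[str, ...]
    text: str
    index: int


@dataclass
class Sentence:
    """Character interval of one sentence, relative to its block's text."""

    block_index: int
    start: int
    end: int


@dataclass
class Mention:
    """A normalized gene mention: a span in a block mapped to an identifier."""

    block_index: int
    start: int
    end: int
    surface: str
    identifier: str


@dataclass
class AnnotationRecord:
    article_id: str
    block_index: int
    start: int
    end: int
    surface: str
    identifier: str


@dataclass
class Document:
    article_id: str
    blocks: list[Block] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    keyword_terms: list[str] = field(default_factory=list)
    abbrev_defs: list[tuple[str, str]] = field(default_factory=list)

    def identifiers(self) -> list[str]:
        """Distinct identifiers in first-mention order."""
        seen: dict[str, None] = {}
        for m in sorted(self.mentions, key=lambda m: (m.block_index, m.start)):
            seen.setdefault(m.identifier, None)
        return list(seen)

    def sentence_of(self, mention: Mention) -> int | None:
        """Index into ``sentences`` of the sentence containing the mention start."""
        for idx, s in enumerate(self.sentences):
            if s.block_index == mention.block_index and s.start <= mention.start < s.end:
                return idx
        return None

    def sentence_text(self, sentence: Sentence) -> str:
        return self.blocks[sentence.block_index].text[sentence.start : sentence.end]


# ---------------------------------------------------------------------------
# Block file dialect


def derive_keyword_terms(blocks: Sequence[Block]) -> list[str]:
    """Split KEYWORD block texts on ``;`` / ``,`` into stripped terms."""
    terms: list[str] = []
    for b in blocks:
        if b.block_type is BlockType.KEYWORD:
            for t in re.split(r"[;,]", b.text):
                t = t.strip()
                if t and t not in terms:
                    terms.append(t)
    return terms


def read_block_document(stream: TextIO | Iterable[str], article_id: str = "") -> Document:
    lines = [ln.rstrip("\n") for ln in stream]
    # A dangling empty line (e.g. from str.split) is not a block opener.
    if len(lines) % 2 == 1 and lines[-1] == "":
        lines.pop()
    blocks: list[Block] = []
    for i in range(0, len(lines), 2):
        type_line = lines[i]
        if i + 1 >= len(lines):
            raise ParseError(
                f"line {i + 1}: block starting here is missing its heading line"
            )
        head, _, text = type_line.partition("\t")
        try:
            btype = BlockType(head)
        except ValueError:
            raise ParseError(f"line {i + 1}: unknown section type {head!r}") from None
        heading_line = lines[i + 1]
        heading_path = (
            tuple(heading_line.split(HEADING_DELIMITER)) if heading_line else ()
        )
        blocks.append(Block(btype, heading_path, text, index=len(blocks)))
    return Document(
        article_id=article_id, blocks=blocks, keyword_terms=derive_keyword_terms(blocks)
    )


def write_block_document(doc: Document, stream: TextIO) -> None:
    for b in doc.blocks:
        stream.write(f"{b.block_type.value}\t{b.text}\n")
        stream.write(HEADING_DELIMITER.join(b.heading_path) + "\n")


def document_to_json(doc: Document) -> str:
    payload = {
        "article_id": doc.article_id,
        "blocks": [
            {
                "block_type": b.block_type.value,
                "heading_path": list(b.heading_path),
                "text": b.text,
                "index": b.index,
            }
            for b in doc.blocks
        ],
        "sentences": [[s.block_index, s.start, s.end] for s in doc.sentences],
        "mentions": [
            [m.block_index, m.start, m.end, m.surface, m.identifier]
            for m in doc.mentions
        ],
        "keyword_terms": doc.keyword_terms,
        "abbrev_defs": [list(p) for p in doc.abbrev_defs],
    }
    return json.dumps(payload, ensure_ascii=False, indent=1)


def document_from_json(text: str) -> Document:
    payload = json.loads(text)
    blocks = [
        Block(BlockType(b["block_type"]), tuple(b["heading_path"]), b["text"], b["index"])
        for b in payload["blocks"]
    ]
    return Document(
        article_id=payload["article_id"],
        blocks=blocks,
        sentences=[Sentence(*s) for s in payload["sentences"]],
        mentions=[Mention(*m) for m in payload["mentions"]],
        keyword_terms=list(payload["keyword_terms"]),
        abbrev_defs=[tuple(p) for p in payload["abbrev_defs"]],
    )


# ---------------------------------------------------------------------------
# Text normalization

_GREEK_NAMES = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}
_GREEK_MAP = dict(_GREEK_NAMES)
for _lower, _name in _GREEK_NAMES.items():
    _GREEK_MAP[_lower.upper()] = _name.capitalize()
_GREEK_RE = re.compile("|".join(map(re.escape, _GREEK_MAP)))


def transliterate_greek(text: str) -> str:
    """Spell out Greek letters (``α`` → ``alpha``); idempotent, other chars kept."""
    return _GREEK_RE.sub(lambda m: _GREEK_MAP[m.group(0)], text)


_RANGE_RE = re.compile(r"^([A-Za-z][A-Za-z_-]*?)(\d+)-([A-Za-z][A-Za-z_-]*?)(\d+)$")


def expand_numeric_range(mention: str, cap: int = 20) -> list[str]:
    """Expand a collapsed range like ``SOCS1-SOCS7`` into its components.

    Only fires when both sides share the same alphabetic stem, the numbers
    strictly increase, and the expansion has at most ``cap`` members;
    otherwise the mention is returned unchanged as a singleton list.
    """
    m = _RANGE_RE.match(mention)
    if not m:
        return [mention]
    stem1, d1, stem2, d2 = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    if stem1 != stem2 or d1 >= d2 or d2 - d1 + 1 > cap:
        return [mention]
    return [f"{stem1}{k}" for k in range(d1, d2 + 1)]


# ---------------------------------------------------------------------------
# Sentence segmentation (rule-based, deterministic)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def _ends_with_abbreviation(prefix: str, abbreviations: Sequence[str]) -> bool:
    low = prefix.lower()
    for abbr in abbreviations:
        a = abbr.lower()
        if low.endswith(a):
            before = low[: -len(a)]
            if not before or before[-1] in " \t(“\"'[":
                return True
    return False


def segment_block_text(
    text: str, abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS
) -> list[tuple[int, int]]:
    """Sentence spans (0-based half-open) covering all non-whitespace text."""
    spans: list[tuple[int, int]] = []
    cursor = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        if _ends_with_abbreviation(text[:end], abbreviations):
            continue
        while cursor < end and text[cursor].isspace():
            cursor += 1
        if cursor < end:
            spans.append((cursor, end))
        cursor = end
    while cursor < len(text) and text[cursor].isspace():
        cursor += 1
    tail_end = len(text)
    while tail_end > cursor and text[tail_end - 1].isspace():
        tail_end -= 1
    if tail_end > cursor:
        spans.append((cursor, tail_end))
    return spans


def segment_sentences(
    doc: Document, abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS
) -> Document:
    """Populate ``doc.sentences`` in place (and return the document)."""
    sentences: list[Sentence] = []
    for b in doc.blocks:
        for start, end in segment_block_text(b.text, abbreviations):
            sentences.append(Sentence(b.index, start, end))
    doc.sentences = sentences
    return doc


# ---------------------------------------------------------------------------
# Standoff annotations


def attach_annotations(doc: Document, records: Iterable[AnnotationRecord]) -> Document:
    """Attach standoff mention records to their blocks, validating spans."""
    for rec in records:
        if not 0 <= rec.block_index < len(doc.blocks):
            raise ValueError(f"annotation references missing block: {rec}")
        text = doc.blocks[rec.block_index].text
        if not (0 <= rec.start < rec.end <= len(text)):
            raise ValueError(f"annotation span out of bounds: {rec}")
        actual = text[rec.start : rec.end]
        if actual != rec.surface:
            logger.warning(
                "surface mismatch at block %d [%d:%d]: %r != %r",
                rec.block_index, rec.start, rec.end, actual, rec.surface,
            )
        doc.mentions.append(
            Mention(rec.block_index, rec.start, rec.end, rec.surface, rec.identifier)
        )
    doc.mentions.sort(key=lambda m: (m.block_index, m.start))
    return doc


_ANNOTATION_HEADER = "article_id\tblock_index\tstart\tend\tsurface\tidentifier"


def read_annotations(stream: TextIO | Iterable[str]) -> list[AnnotationRecord]:
    records: list[AnnotationRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols[:2] == ["article_id", "block_index"]:
            continue
        if len(cols) != 6:
            raise ParseError(f"line {lineno}: expected 6 tab-separated columns")
        records.append(
            AnnotationRecord(cols[0], int(cols[1]), int(cols[2]), int(cols[3]), cols[4], cols[5])
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], stream: TextIO) -> None:
    stream.write(_ANNOTATION_HEADER + "\n")
    for r in records:
        stream.write(
            f"{r.article_id}\t{r.block_index}\t{r.start}\t{r.end}\t{r.surface}\t{r.identifier}\n"
        )


# ---------------------------------------------------------------------------
# Abbreviation definitions ("Full Name (ABBR)" parentheticals)

_PAREN_RE = re.compile(r"\(([A-Za-z][A-Za-z0-9-]{1,9})\)")


def extract_abbreviations(doc: Document) -> Document:
    """Detect ``Full Name (ABBR)`` pairs with an initial-letter heuristic.

    The candidate long form is the run of words before the parenthetical;
    a pair is kept when the abbreviation's first letter matches the initial
    of one of the last ``len(abbr)+1`` words.
    """
    pairs: list[tuple[str, str]] = []
    for b in doc.blocks:
        for m in _PAREN_RE.finditer(b.text):
            abbr = m.group(1)
            if abbr.lower() == abbr:  # require at least one capital
                continue
            prefix_words = re.findall(r"[A-Za-z0-9-]+", b.text[: m.start()])
            window = prefix_words[-(len(abbr) + 1) :]
            for k, w in enumerate(window):
                if w[0].lower() == abbr[0].lower():
                    full = " ".join(window[k:])
                    if full.lower() != abbr.lower() and (full, abbr) not in pairs:
                        pairs.append((full, abbr))
                    break
    doc.abbrev_defs = pairs
    return doc
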
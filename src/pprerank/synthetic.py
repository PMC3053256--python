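"""Synthetic block-structured articles with planted interaction signal.

The generator emulates the statistical structure the ranking and
re-ranking stages exploit in real full-text articles: a handful of true
interactors that are frequent in the Results section, appear in the title,
keywords and figure captions, and co-occur with each other in sentences at
a boosted rate; background genes with moderate scattered frequency; one
frequent "focus" gene that is discussed throughout without interacting;
and one sparse interactor that is mentioned rarely but almost always
alongside the other interactors — the case co-occurrence re-ranking is
designed to rescue.

Sentences are templated, not natural language: the downstream pipeline
consumes standoff annotations, so linguistic realism is irrelevant while
offset bookkeeping must be exact.  Same config (including seed) twice
yields byte-identical output.
"""

from __future__ import annotations

import itertools
import math
import random
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

from pprerank.corpus_io import (
    AnnotationRecord,
    Block,
    BlockType,
    Document,
    attach_annotations,
    derive_keyword_terms,
    extract_abbreviations,
    segment_sentences,
    write_annotations,
    write_block_document,
)

_PAIR_TEMPLATES = (
    "{a} interacts with {b} in vitro.",
    "{a} co-immunoprecipitated with {b}.",
    "Binding of {a} to {b} was observed.",
    "{a} forms a stable complex with {b}.",
)
_SINGLE_TEMPLATES = (
    "{a} was detected in the lysates.",
    "Expression of {a} increased markedly.",
    "{a} is a key regulator of this pathway.",
    "Knockdown of {a} reduced the signal.",
)
_FILLER_SENTENCES = (
    "The samples were analyzed under standard conditions.",
    "Cells were cultured as described previously.",
    "Statistical analysis confirmed the trend.",
    "These data are consistent with previous reports.",
)

_BODY_SECTIONS = ("ABSTRACT", "Introduction", "Results", "Conclusions")
_PAIR_SECTION_WEIGHTS = {"Results": 0.7, "Introduction": 0.15, "ABSTRACT": 0.15}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic article."""

    n_identifiers: int = 9
    n_interactors: int = 4
    n_gold_pairs: int = 3
    #: (min, max) sentence counts per section, filler-padded to the minimum.
    sentence_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "ABSTRACT": (3, 5),
            "Introduction": (4, 6),
            "Results": (10, 14),
            "Conclusions": (2, 4),
        }
    )
    #: expected single-mention counts per identifier class; the sparse rate
    #: applies to the later half of the interactors — the weakly mentioned
    #: true interactors that frequency ranking underrates
    interactor_mention_rate: float = 8.0
    sparse_interactor_rate: float = 1.0
    background_mention_rate: float = 5.0
    focus_mention_rate: float = 5.0
    #: expected same-sentence co-mentions per interactor pair (before boost)
    pair_mention_rate: float = 0.4
    #: expected co-mentions for sampled background pairs
    background_pair_rate: float = 0.1
    #: multiplier on pair_mention_rate for gold pairs
    cooccurrence_boost: float = 4.0
    #: placement weights for interactor single mentions
    section_bias: dict[str, float] = field(
        default_factory=lambda: {
            "TITLE": 0.05,
            "ABSTRACT": 0.10,
            "Introduction": 0.10,
            "Results": 0.55,
            "Conclusions": 0.10,
            "FIGURE": 0.10,
        }
    )
    keyword_fraction: float = 0.5
    figure_ref_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_interactors > self.n_identifiers:
            raise ValueError("n_interactors exceeds n_identifiers")
        if self.n_interactors < 2 and self.n_gold_pairs > 0:
            raise ValueError("gold pairs require at least two interactors")
        max_pairs = self.n_interactors * (self.n_interactors - 1) // 2
        if self.n_gold_pairs > max_pairs:
            raise ValueError(
                f"n_gold_pairs={self.n_gold_pairs} exceeds the {max_pairs} interactor pairs"
            )
        rates = (
            self.interactor_mention_rate,
            self.sparse_interactor_rate,
            self.background_mention_rate,
            self.focus_mention_rate,
            self.pair_mention_rate,
            self.background_pair_rate,
            self.cooccurrence_boost,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        for frac in (self.keyword_fraction, self.figure_ref_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(w < 0 for w in self.section_bias.values()):
            raise ValueError("section bias weights must be non-negative")


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, p = 0, rng.random()
    while p > limit:
        k += 1
        p *= rng.random()
    return k


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    keys = list(weights)
    return rng.choices(keys, weights=[weights[k] for k in keys], k=1)[0]


# A sentence is a list of parts; each part is (text, identifier-or-None).
Parts = list[tuple[str, str | None]]


def _fill_template(template: str, **ids: str) -> Parts:
    parts: Parts = []
    rest = template
    while rest:
        starts = {rest.index("{" + k + "}"): k for k in ids if "{" + k + "}" in rest}
        if not starts:
            parts.append((rest, None))
            break
        pos = min(starts)
        key = starts[pos]
        if pos:
            parts.append((rest[:pos], None))
        parts.append((ids[key], ids[key]))
        rest = rest[pos + len(key) + 2 :]
    return parts


def _render_block(sentences: list[Parts]) -> tuple[str, list[tuple[int, int, str]]]:
    """Join sentences with spaces; return text and (start, end, id) mentions."""
    text_chunks: list[str] = []
    mentions: list[tuple[int, int, str]] = []
    offset = 0
    for si, parts in enumerate(sentences):
        if si:
            text_chunks.append(" ")
            offset += 1
        for chunk, ident in parts:
            if ident is not None:
                mentions.append((offset, offset + len(chunk), ident))
            text_chunks.append(chunk)
            offset += len(chunk)
    return "".join(text_chunks), mentions


def generate_article(
    cfg: SynthConfig, article_id: str = "synth0000"
) -> tuple[Document, set[str], set[tuple[str, str]]]:
    """One article plus its gold interactor set and gold pair set."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    interactors = [f"P{10001 + k}" for k in range(cfg.n_interactors)]
    backgrounds = [f"Q{20001 + k}" for k in range(cfg.n_identifiers - cfg.n_interactors)]
    focus = backgrounds[0] if backgrounds else None
    sparse = set(interactors[(cfg.n_interactors + 1) // 2 :])

    all_int_pairs = [tuple(sorted(p)) for p in itertools.combinations(interactors, 2)]
    gold_pairs = set(rng.sample(all_int_pairs, cfg.n_gold_pairs)) if all_int_pairs else set()

    section_sents: dict[str, list[Parts]] = {s: [] for s in _BODY_SECTIONS}
    figure_sents: list[Parts] = []

    # --- pair co-mention sentences -------------------------------------
    pair_events: list[tuple[str, str]] = []
    pair_totals: dict[tuple[str, str], int] = {}
    for pair in all_int_pairs:
        lam = cfg.pair_mention_rate * (
            cfg.cooccurrence_boost if pair in gold_pairs else 1.0
        )
        k = _poisson(rng, lam)
        pair_totals[pair] = k
        pair_events.extend([pair] * k)
    everyone = interactors + backgrounds
    for bg in backgrounds:
        partner = rng.choice([x for x in everyone if x != bg])
        k = _poisson(rng, cfg.background_pair_rate)
        pair = tuple(sorted((bg, partner)))
        pair_totals[pair] = pair_totals.get(pair, 0) + k
        pair_events.extend([pair] * k)
    for a, b in pair_events:
        section = _weighted_choice(rng, _PAIR_SECTION_WEIGHTS)
        template = rng.choice(_PAIR_TEMPLATES)
        parts = _fill_template(template, a=a, b=b)
        if section == "Results" and rng.random() < cfg.figure_ref_fraction:
            last_text = parts[-1][0]
            parts[-1] = (last_text.rstrip(".") + " (Figure 1).", None)
        section_sents[section].append(parts)

    # --- single-mention sentences --------------------------------------
    def rate_of(ident: str) -> float:
        if ident == focus:
            return cfg.focus_mention_rate
        if ident in sparse:
            return cfg.sparse_interactor_rate
        if ident in interactors:
            return cfg.interactor_mention_rate
        return cfg.background_mention_rate

    title_mention: str | None = None
    for ident in everyone:
        n_single = max(1, _poisson(rng, rate_of(ident)))
        for _ in range(n_single):
            if ident in interactors:
                target = _weighted_choice(rng, cfg.section_bias)
            else:
                target = rng.choice(_BODY_SECTIONS)
            if target == "TITLE":
                if title_mention is None:
                    title_mention = ident
                    continue
                target = "ABSTRACT"
            parts = _fill_template(rng.choice(_SINGLE_TEMPLATES), a=ident)
            if target == "FIGURE":
                parts = [("Figure 2. ", None)] + parts
                figure_sents.append(parts)
            else:
                section_sents[target].append(parts)

    # --- indicator sentence in the Conclusions -------------------------
    concl_subject = rng.choice(interactors)
    section_sents["Conclusions"].insert(
        0,
        _fill_template("We conclude that {a} plays a central role in this process.",
                       a=concl_subject),
    )

    # --- figure 1 caption: the most co-mentioned pair -------------------
    if pair_totals and max(pair_totals.values()) > 0:
        cap_pair = min(pair_totals, key=lambda p: (-pair_totals[p], p))
        figure_sents.insert(
            0,
            [("Figure 1. ", None)]
            + _fill_template("Co-immunoprecipitation of {a} with {b}.",
                             a=cap_pair[0], b=cap_pair[1]),
        )

    # --- shuffle and pad sections to their sentence ranges ---------------
    for section in _BODY_SECTIONS:
        rng.shuffle(section_sents[section])
        lo, hi = cfg.sentence_ranges.get(section, (0, 0))
        target = rng.randint(lo, hi) if hi >= lo else lo
        while len(section_sents[section]) < target:
            section_sents[section].append([(rng.choice(_FILLER_SENTENCES), None)])

    # --- assemble blocks -------------------------------------------------
    if title_mention is None:
        title_mention = rng.choice(interactors) if interactors else None
    if title_mention is not None:
        title_parts = _fill_template(
            "Functional analysis of {a} signalling.", a=title_mention
        )
    else:
        title_parts = [("A descriptive study of cellular signalling.", None)]

    n_kw = round(cfg.keyword_fraction * cfg.n_interactors)
    keyword_terms = sorted(rng.sample(interactors, n_kw)) if n_kw else []

    heading_subject = rng.choice(interactors) if interactors else "signalling"
    specs: list[tuple[BlockType, tuple[str, ...], list[Parts]]] = [
        (BlockType.TITLE, (), [title_parts]),
        (BlockType.ABSTRACT, (), section_sents["ABSTRACT"]),
        (BlockType.KEYWORD, (), [[("; ".join(keyword_terms), None)]] if keyword_terms else [[("signalling", None)]]),
        (BlockType.BODY, ("1 Introduction",), section_sents["Introduction"]),
        (
            BlockType.BODY,
            ("3 Results", f"3.1 {heading_subject} interacts with its partners"),
            section_sents["Results"],
        ),
        (BlockType.BODY, ("5 Conclusions",), section_sents["Conclusions"]),
        (BlockType.FIGURE, (), figure_sents or [[("Figure 1. Workflow overview.", None)]]),
    ]

    blocks: list[Block] = []
    records: list[AnnotationRecord] = []
    for btype, heading, sentences in specs:
        text, mentions = _render_block(sentences)
        idx = len(blocks)
        blocks.append(Block(btype, heading, text, idx))
        for start, end, ident in mentions:
            records.append(AnnotationRecord(article_id, idx, start, end, ident, ident))

    doc = Document(article_id=article_id, blocks=blocks,
                   keyword_terms=derive_keyword_terms(blocks))
    segment_sentences(doc)
    extract_abbreviations(doc)
    attach_annotations(doc, records)
    return doc, set(interactors), gold_pairs


def _child_seed(seed: int, index: int) -> int:
    return zlib.crc32(f"{seed}:{index}".encode()) % (2**31)


def generate_corpus(
    cfg: SynthConfig,
    n_articles: int,
    out_dir: str | Path | None = None,
) -> list[tuple[Document, set[str], set[tuple[str, str]]]]:
    """Independent articles under per-article seeds derived from cfg.seed."""
    corpus = []
    for k in range(n_articles):
        article_cfg = replace(cfg, seed=_child_seed(cfg.seed, k))
        corpus.append(generate_article(article_cfg, article_id=f"synth{k:04d}"))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with (out / "gold_interactors.tsv").open("w") as gi, (
            out / "gold_pairs.tsv"
        ).open("w") as gp:
            gi.write("article_id\tidentifier\n")
            gp.write("article_id\tid_a\tid_b\n")
            for doc, gold, pairs in corpus:
                with (out / f"{doc.article_id}.blocks.txt").open("w") as fh:
                    write_block_document(doc, fh)
                with (out / f"{doc.article_id}.ann.tsv").open("w") as fh:
                    write_annotations(
                        [
                            AnnotationRecord(
                                doc.article_id, m.block_index, m.start, m.end,
                                m.surface, m.identifier,
                            )
                            for m in doc.mentions
                        ],
                        fh,
                    )
                for ident in sorted(gold):
                    gi.write(f"{doc.article_id}\t{ident}\n")
                for a, b in sorted(pairs):
                    gp.write(f"{doc.article_id}\t{a}\t{b}\n")
    return corpus
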
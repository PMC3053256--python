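"""End-to-end drivers: rank, re-rank, pair-score, evaluate.

Each driver is deterministic given its inputs and configuration and logs
per-stage counts, so a run can be reproduced exactly from its resolved
config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pprerank.association import build_cooccurrence_stats, make_associator
from pprerank.corpus_io import Document
from pprerank.evalmetrics import ArticleEval, auc_ipr_ranked
from pprerank.ipt import ScoredPair, rank_pairs
from pprerank.ranking import (
    AccuracyProfile,
    RankedList,
    extract_features,
    rank_frequency_baseline,
    rank_with_model,
)
from pprerank.rerank import (
    RerankedList,
    find_optimal_reranking,
    generate_candidate_lists,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    ranker: str = "freq"  # "freq" or "model"
    model: object | None = None
    profile: AccuracyProfile = field(default_factory=AccuracyProfile.constant)
    include_own: bool = True
    floor_epsilon: float = 1e-6
    association_backend: str = "mi"
    ipt_mode: str = "mi_rerank"
    ipt_rank_mode: str = "reranked"  # "reranked" or "svm"

    def validate(self) -> None:
        if self.ranker not in ("freq", "model"):
            raise ValueError(f"unknown ranker {self.ranker!r}")
        if self.ranker == "model" and self.model is None:
            raise ValueError("ranker='model' requires a model instance")


def _initial_ranking(doc: Document, cfg: PipelineConfig) -> RankedList:
    if cfg.ranker == "freq":
        return rank_frequency_baseline(doc)
    features = {ident: extract_features(doc, ident) for ident in doc.identifiers()}
    return rank_with_model(
        cfg.model, features, article_id=doc.article_id,
        baseline=rank_frequency_baseline(doc),
    )


def run_int(doc: Document, cfg: PipelineConfig) -> RerankedList:
    """Initial ranking followed by co-occurrence re-ranking."""
    cfg.validate()
    r = _initial_ranking(doc, cfg)
    stats = build_cooccurrence_stats(doc)
    assoc = make_associator(stats, cfg.association_backend)
    L = generate_candidate_lists(r, assoc)
    reranked = find_optimal_reranking(r, L, cfg.profile, include_own=cfg.include_own)
    logger.info(
        "%s: %d identifiers, %d co-occurring pairs, overall score %.3g",
        doc.article_id, len(r), len(stats.pair_count), reranked.overall_score,
    )
    return reranked


def run_ipt(doc: Document, cfg: PipelineConfig) -> tuple[RerankedList, list[ScoredPair]]:
    """Re-ranked interactor list plus the scored, ordered pair list."""
    cfg.validate()
    r = _initial_ranking(doc, cfg)
    stats = build_cooccurrence_stats(doc)
    assoc = make_associator(stats, cfg.association_backend)
    L = generate_candidate_lists(r, assoc)
    reranked = find_optimal_reranking(r, L, cfg.profile, include_own=cfg.include_own)
    pairs = rank_pairs(
        reranked, stats, L, cfg.profile,
        mode=cfg.ipt_mode, rank_mode=cfg.ipt_rank_mode, svm_ranking=r,
        floor_epsilon=cfg.floor_epsilon, include_own=cfg.include_own,
    )
    logger.info("%s: %d candidate pairs", doc.article_id, len(pairs))
    return reranked, pairs


def run_eval(
    outputs: dict[str, list], gold: dict[str, set], label: str = ""
) -> tuple[list[ArticleEval], float]:
    """Per-article AUC iP/R plus the corpus mean.

    ``outputs`` maps article_id to its ranked items (identifiers or pairs);
    ``gold`` maps article_id to the gold set of the same item type.
    Articles without a gold entry are skipped with a warning.
    """
    rows: list[ArticleEval] = []
    for article_id, ranked in sorted(outputs.items()):
        gold_set = gold.get(article_id)
        if not gold_set:
            logger.warning("no gold for article %s; skipped", article_id)
            continue
        rows.append(
            ArticleEval(
                article_id=article_id,
                auc=auc_ipr_ranked(ranked, gold_set),
                n_gold=len(gold_set),
                n_returned=len(ranked),
            )
        )
    mean = sum(r.auc for r in rows) / len(rows) if rows else 0.0
    if label:
        logger.info("%s: mean AUC iP/R %.4f over %d articles", label, mean, len(rows))
    return rows, mean
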
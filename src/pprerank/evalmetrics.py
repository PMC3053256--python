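"""Ranked-retrieval evaluation: interpolated precision/recall AUC, t-test.

For a ranked output list against a gold set, the iP/R curve records, at
every correct hit j, the recall r_j = j / |gold| and the raw precision
j / position.  Interpolated precision at recall r is the maximum raw
precision at any recall >= r, and

    AUC iP/R = sum_j  p_interp(r_j) * (r_j - r_{j-1}),   r_0 = 0.

The recall denominator is the gold set size, so gold items never returned
truncate the curve and cap the AUC below 1.  Duplicates in a ranked list
count once; later occurrences are wrong hits.

The two-sample t statistic for comparing mean AUCs of two system
configurations uses the unpooled (Welch) standard error.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence, TextIO

#: Printed one-sided critical value at df=89, 95% confidence.
T_THRESHOLD = 1.67


@dataclass
class PRCurve:
    """(recall, raw precision) at each correct hit, plus the gold size."""

    hits: list[tuple[float, float]]
    n_gold: int


def pr_curve(ranked: Sequence[Hashable], gold: set) -> PRCurve:
    if not gold:
        raise ValueError("gold set must be nonempty")
    hits: list[tuple[float, float]] = []
    found: set = set()
    position = 0
    for item in ranked:
        position += 1
        if item in gold and item not in found:
            found.add(item)
            j = len(found)
            hits.append((j / len(gold), j / position))
    return PRCurve(hits=hits, n_gold=len(gold))


def auc_ipr(curve: PRCurve) -> float:
    """Area under the interpolated precision/recall curve, in [0, 1]."""
    if not curve.hits:
        return 0.0
    # interpolated precision: max raw precision at this or any later hit
    interp: list[float] = []
    running = 0.0
    for _, p in reversed(curve.hits):
        running = max(running, p)
        interp.append(running)
    interp.reverse()
    area = 0.0
    prev_r = 0.0
    for (r, _), p in zip(curve.hits, interp):
        area += p * (r - prev_r)
        prev_r = r
    return area


def auc_ipr_ranked(ranked: Sequence[Hashable], gold: set) -> float:
    return auc_ipr(pr_curve(ranked, gold))


def two_sample_t(
    mean_a: float,
    mean_b: float,
    sd_a: float,
    sd_b: float,
    n_a: int,
    n_b: int,
) -> float:
    """Absolute standardized difference of two independent sample means."""
    if n_a < 2 or n_b < 2:
        raise ValueError("both sample sizes must be >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("at least one standard deviation must be positive")
    return abs(mean_a - mean_b) / math.sqrt(sd_a**2 / n_a + sd_b**2 / n_b)


def is_significant(t: float, threshold: float = T_THRESHOLD) -> bool:
    return t > threshold


@dataclass
class ArticleEval:
    article_id: str
    auc: float
    n_gold: int
    n_returned: int


def write_eval_report(rows: Iterable[ArticleEval], stream: TextIO) -> None:
    stream.write("article_id\tauc_ipr\tn_gold\tn_returned\n")
    aucs: list[float] = []
    for r in rows:
        aucs.append(r.auc)
        stream.write(f"{r.article_id}\t{r.auc!r}\t{r.n_gold}\t{r.n_returned}\n")
    if aucs:
        mean = statistics.fmean(aucs)
        sd = statistics.stdev(aucs) if len(aucs) > 1 else 0.0
        stream.write(f"# corpus mean={mean!r} sd={sd!r} n={len(aucs)}\n")
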
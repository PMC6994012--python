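"""Scoring of ranked candidate-synonym lists against gold concept links.

Metrics: mean reciprocal rank (MRR), coverage (fraction of queries with at
least one correct synonym in the top-k list), top-1 accuracy, and the mean
Jaro-Winkler similarity of the correct top-1 pairs (how lexically similar are
the synonyms a model finds first?).  A corpus-level statistic — the mean
Jaro-Winkler similarity between each eligible mention and all of its gold
synonyms — characterizes how lexically hard the data itself is.  Model pairs
are compared on the top-1 and coverage proportions with a two-sided pooled
two-proportion z-test; no significance test is defined for MRR.

Only *eligible* queries are evaluated: mentions with at least one synonym
(same concept, different normalized surface) present in their own data fold.
A query whose list contains no correct candidate contributes reciprocal rank
0, so MRR is averaged over all eligible queries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from scipy.stats import norm

from .corpus import CUI_LESS, MentionAnnotation, normalize_surface
from .discovery import RankedList
from .lexical import jaro_winkler

logger = logging.getLogger(__name__)

# Manual error taxonomy for annotating incorrect top-1 pairs; labels only, no
# automatic classifier.
ERROR_CATEGORIES = (
    "synonym-overlap",
    "abbreviation",
    "morphological-or-lexical-overlap",
    "no-relation",
    "similar-concepts",
)


def is_synonym(
    m_q: MentionAnnotation,
    m_c: MentionAnnotation,
    non_concept_markers: frozenset[str] = frozenset(),
) -> bool:
    """True iff the two mentions link to the same concept with different
    normalized surfaces.  CUI-less marks the *absence* of a concept, so two
    CUI-less mentions are never synonyms; the same holds for any declared
    non-concept marker."""
    if m_q.concept != m_c.concept:
        return False
    if m_q.concept == CUI_LESS or m_q.concept in non_concept_markers:
        return False
    return normalize_surface(m_q.surface) != normalize_surface(m_c.surface)


def eligible_queries(
    mentions: Sequence[MentionAnnotation],
    non_concept_markers: frozenset[str] = frozenset(),
) -> list[MentionAnnotation]:
    """Mentions with at least one synonym in their own fold."""
    by_fold_concept: dict[tuple[str, str], list[MentionAnnotation]] = {}
    for m in mentions:
        by_fold_concept.setdefault((m.fold, m.concept), []).append(m)
    out = []
    for m in mentions:
        if m.concept == CUI_LESS or m.concept in non_concept_markers:
            continue
        group = by_fold_concept[(m.fold, m.concept)]
        if any(is_synonym(m, other, non_concept_markers) for other in group):
            out.append(m)
    return out


@dataclass(frozen=True)
class QueryRecord:
    """Per-query audit row."""

    query_id: str
    first_correct_rank: int | None
    top1_correct: bool
    top1_candidate: str | None
    jw_top1: float | None


@dataclass(frozen=True)
class EvalReport:
    n_queries: int
    mrr: float
    coverage: float
    top1: float
    jw_top1_mean: float | None
    records: tuple[QueryRecord, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        for name in ("mrr", "coverage", "top1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if not (self.top1 <= self.mrr + 1e-12 and self.mrr <= self.coverage + 1e-12):
            raise ValueError(
                f"metric ordering violated: top1={self.top1} mrr={self.mrr} "
                f"coverage={self.coverage}"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_queries": self.n_queries,
            "mrr": self.mrr,
            "coverage": self.coverage,
            "top1": self.top1,
            "jw_top1_mean": self.jw_top1_mean,
            "queries": [
                {
                    "query_id": r.query_id,
                    "first_correct_rank": r.first_correct_rank,
                    "top1_correct": r.top1_correct,
                    "top1_candidate": r.top1_candidate,
                    "jw_top1": r.jw_top1,
                }
                for r in self.records
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvalReport":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        records = tuple(
            QueryRecord(
                query_id=r["query_id"],
                first_correct_rank=r["first_correct_rank"],
                top1_correct=r["top1_correct"],
                top1_candidate=r["top1_candidate"],
                jw_top1=r["jw_top1"],
            )
            for r in payload.get("queries", [])
        )
        return cls(
            n_queries=payload["n_queries"],
            mrr=payload["mrr"],
            coverage=payload["coverage"],
            top1=payload["top1"],
            jw_top1_mean=payload["jw_top1_mean"],
            records=records,
        )


def score_rankings(
    rankings: Mapping[str, RankedList],
    mentions: Sequence[MentionAnnotation],
    k: int = 50,
    non_concept_markers: frozenset[str] = frozenset(),
) -> EvalReport:
    """Score ranked lists over the eligible-query set.

    Reciprocal rank is 1/r for the first correct candidate at rank r ≤ k,
    else 0; coverage counts any correct candidate in the top k; top-1 counts
    a correct first candidate.  jw_top1_mean averages the Jaro-Winkler
    similarity of (query, top-1) surfaces over queries whose top-1 is
    correct, and is None when there are none.  An eligible query without a
    ranking counts as a miss (reciprocal rank 0) and is logged.
    """
    by_id = {m.mention_id: m for m in mentions}
    eligible = eligible_queries(mentions, non_concept_markers)
    records: list[QueryRecord] = []
    rr_sum = 0.0
    n_cov = 0
    n_top1 = 0
    jw_values: list[float] = []
    for query in eligible:
        ranking = rankings.get(query.mention_id)
        if ranking is None:
            logger.warning("no ranking for eligible query %s; scored as miss", query.mention_id)
            records.append(QueryRecord(query.mention_id, None, False, None, None))
            continue
        first_rank: int | None = None
        top1_candidate: str | None = None
        for rank, (cid, _score) in enumerate(ranking.entries[:k], start=1):
            if rank == 1:
                top1_candidate = cid
            cand = by_id.get(cid)
            if cand is not None and is_synonym(query, cand, non_concept_markers):
                first_rank = rank
                break
        top1_correct = first_rank == 1
        jw = None
        if top1_correct:
            jw = jaro_winkler(query.surface, by_id[top1_candidate].surface)
            jw_values.append(jw)
            n_top1 += 1
        if first_rank is not None:
            rr_sum += 1.0 / first_rank
            n_cov += 1
        records.append(QueryRecord(query.mention_id, first_rank, top1_correct, top1_candidate, jw))
    n = len(eligible)
    return EvalReport(
        n_queries=n,
        mrr=rr_sum / n if n else 0.0,
        coverage=n_cov / n if n else 0.0,
        top1=n_top1 / n if n else 0.0,
        jw_top1_mean=(sum(jw_values) / len(jw_values)) if jw_values else None,
        records=tuple(records),
    )


def mean_gold_jw(
    mentions: Sequence[MentionAnnotation],
    non_concept_markers: frozenset[str] = frozenset(),
) -> float:
    """Mean over eligible mentions of the mean Jaro-Winkler similarity to each
    of their gold synonyms (same fold, same concept, different surface).
    Characterizes the lexical difficulty of the corpus itself."""
    eligible = eligible_queries(mentions, non_concept_markers)
    by_fold_concept: dict[tuple[str, str], list[MentionAnnotation]] = {}
    for m in mentions:
        by_fold_concept.setdefault((m.fold, m.concept), []).append(m)
    per_mention: list[float] = []
    for m in eligible:
        sims = [
            jaro_winkler(m.surface, other.surface)
            for other in by_fold_concept[(m.fold, m.concept)]
            if is_synonym(m, other, non_concept_markers)
        ]
        per_mention.append(sum(sims) / len(sims))
    return sum(per_mention) / len(per_mention) if per_mention else 0.0


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided pooled two-proportion z-test.

    z = (p1 - p2) / sqrt(p̂ (1-p̂) (1/n1 + 1/n2)) with p̂ the pooled
    proportion; p-value from the standard normal.  When the pooled proportion
    is 0 or 1 the statistic is degenerate and (0.0, 1.0) is returned by
    convention — identical saturated samples carry no evidence either way.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("sample size must be >= 1")
        if not 0 <= x <= n:
            raise ValueError(f"successes {x} outside [0, {n}]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = (pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)) ** 0.5
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return float(z), p


def compare_reports(a: EvalReport, b: EvalReport) -> dict[str, dict[str, float]]:
    """Significance comparison of two models on the proportions the test is
    defined for: top-1 accuracy and coverage."""
    if a.n_queries < 1 or b.n_queries < 1:
        raise ValueError("cannot compare empty reports")
    out = {}
    for metric in ("top1", "coverage"):
        xa = round(getattr(a, metric) * a.n_queries)
        xb = round(getattr(b, metric) * b.n_queries)
        z, p = two_proportion_z_test(xa, a.n_queries, xb, b.n_queries)
        out[metric] = {"z": z, "p": p}
    return out
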
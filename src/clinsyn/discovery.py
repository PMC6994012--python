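"""Ranked candidate-synonym lists.

Every mention acts as a query; all other mentions in the same data fold are
candidates, ranked by cosine similarity of their representations (or by an
arbitrary lexical scoring function for the string baselines).  Candidates
whose normalized surface equals the query's are excluded — identical strings
are the same term, not a discovered synonym — but distinct mentions that
share a surface with *each other* all stay in the pool.  Lists are truncated
to the top k (default 50) after exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .corpus import MentionAnnotation, normalize_surface
from .encoders import MentionVector

logger = logging.getLogger(__name__)

DEFAULT_K = 50

NEG_INF = float("-inf")


@dataclass(frozen=True)
class RankedList:
    """Ordered candidate synonyms for one query mention."""

    query_id: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError(f"{self.query_id}: scores not non-increasing")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; a zero-norm vector yields -inf so degenerate
    representations sort last instead of erroring."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return NEG_INF
    return float(u @ v / (nu * nv))


def _vector_of(rep) -> np.ndarray | None:
    if rep is None:
        return None
    return rep.vector if isinstance(rep, MentionVector) else np.asarray(rep, dtype=float)


def rank_candidates(
    query: MentionAnnotation,
    pool: Sequence[MentionAnnotation],
    representations: Mapping[str, MentionVector | np.ndarray | None] | None = None,
    k: int = DEFAULT_K,
    score_fn: Callable[[str, str], float] | None = None,
) -> RankedList:
    """Rank one query's candidates.

    Exactly one of ``representations`` (cosine ranking) or ``score_fn``
    (surface-based scoring, e.g. the character n-gram baseline) must be
    given.  Exclusions: candidates outside the query's fold, the query
    itself, candidates with the query's normalized surface, and candidates
    without a representation.  Ties break by ascending mention_id.
    """
    if (representations is None) == (score_fn is None):
        raise ValueError("provide exactly one of representations or score_fn")
    qsurf = normalize_surface(query.surface)
    qvec = None
    if representations is not None:
        qvec = _vector_of(representations.get(query.mention_id))
        if qvec is None:
            raise KeyError(f"query {query.mention_id} has no representation")
    scored: list[tuple[float, str]] = []
    for cand in pool:
        if cand.mention_id == query.mention_id or cand.fold != query.fold:
            continue
        if normalize_surface(cand.surface) == qsurf:
            continue
        if representations is not None:
            cvec = _vector_of(representations.get(cand.mention_id))
            if cvec is None:
                continue
            score = cosine(qvec, cvec)
        else:
            score = score_fn(query.surface, cand.surface)
        scored.append((score, cand.mention_id))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return RankedList(
        query_id=query.mention_id,
        entries=tuple((mid, s) for s, mid in scored[:k]),
    )


def rank_all(
    mentions: Sequence[MentionAnnotation],
    representations: Mapping[str, MentionVector | np.ndarray | None] | None = None,
    k: int = DEFAULT_K,
    score_fn: Callable[[str, str], float] | None = None,
) -> dict[str, RankedList]:
    """One RankedList per mention with a present representation.

    Queries without a representation are skipped with a log entry; the result
    is independent of the input mention ordering.
    """
    ordered = sorted(mentions, key=lambda m: m.mention_id)
    by_fold: dict[str, list[MentionAnnotation]] = {}
    for m in ordered:
        by_fold.setdefault(m.fold, []).append(m)
    out: dict[str, RankedList] = {}
    skipped = 0
    for m in ordered:
        if representations is not None and _vector_of(representations.get(m.mention_id)) is None:
            skipped += 1
            continue
        out[m.mention_id] = rank_candidates(
            m, by_fold[m.fold], representations=representations, k=k, score_fn=score_fn
        )
    if skipped:
        logger.info("rank_all: skipped %d query mention(s) without representations", skipped)
    return out


# ---------------------------------------------------------------------------
# Ranking serialization (diffable TSV)
# ---------------------------------------------------------------------------


def write_rankings(rankings: Mapping[str, RankedList], path: str | Path) -> None:
    """query_id, rank, candidate_id, score (6 decimals), sorted by query then
    rank — stable for diffing across runs."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("query_id\trank\tcandidate_id\tscore\n")
        for qid in sorted(rankings):
            for rank, (cid, score) in enumerate(rankings[qid].entries, start=1):
                fh.write(f"{qid}\t{rank}\t{cid}\t{score:.6f}\n")


def read_rankings(path: str | Path) -> dict[str, RankedList]:
    grouped: dict[str, list[tuple[str, float]]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("query_id"):
            raise ValueError(f"{path}: missing rankings header")
        for line in fh:
            if not line.strip():
                continue
            qid, _rank, cid, score = line.rstrip("\n").split("\t")
            grouped.setdefault(qid, []).append((cid, float(score)))
    return {qid: RankedList(query_id=qid, entries=tuple(rows)) for qid, rows in grouped.items()}
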
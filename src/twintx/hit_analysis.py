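"""Best-hit filtering, Ortholog Hit Ratio and assembly summary statistics.

Annotation hits are ranked into four tiers by overlap and identity:
rank 1 = overlap >= 70% and identity >= 50%, rank 2 = high overlap only,
rank 3 = high identity only, rank 4 = neither; only the best tier present
is kept per transcript.  The Ortholog Hit Ratio (OHR) of a transcript is
the ungapped alignment length divided by the full length of the hit
(reference) sequence — 1.0 means the transcript covers the entire
reference — and for multi-hit transcripts the hit with the best OHR is
retained.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AlignmentHit, SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "HitCategory",
    "OHRRecord",
    "AssemblyStats",
    "categorize_hit",
    "best_hits_filter",
    "ortholog_hit_ratio",
    "assembly_stats",
    "ohr_table",
    "ohr_summary",
]

OVERLAP_THRESHOLD = 70.0  # percent of the query covered by the alignment
IDENTITY_THRESHOLD = 50.0  # percent identity among aligned columns


@dataclass(frozen=True)
class HitCategory:
    """One of the four best-hit tiers; rank 1 is best."""

    rank: int
    overlap_high: bool
    identity_high: bool


@dataclass(frozen=True)
class OHRRecord:
    """Best Ortholog Hit Ratio of one transcript."""

    transcript_id: str
    best_subject_id: str
    ohr: float
    n_hits_considered: int


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_bp: int
    mean_length: float
    median_length: float
    n50_length: int


def categorize_hit(hit: AlignmentHit) -> HitCategory:
    """Assign a hit to its overlap/identity tier (thresholds applied as >=)."""
    overlap_high = hit.query_overlap_pct >= OVERLAP_THRESHOLD
    identity_high = hit.pct_identity >= IDENTITY_THRESHOLD
    rank = {(True, True): 1, (True, False): 2,
            (False, True): 3, (False, False): 4}[(overlap_high, identity_high)]
    return HitCategory(rank=rank, overlap_high=overlap_high,
                       identity_high=identity_high)


def best_hits_filter(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    """Keep, per query, exactly the hits of the best tier present.

    Within the retained list hits are ordered by bit score descending,
    ties broken by subject id for determinism.
    """
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for hit in hits:
        by_query[hit.query_id].append(hit)
    out: dict[str, list[AlignmentHit]] = {}
    for qid, qhits in by_query.items():
        best_rank = min(categorize_hit(h).rank for h in qhits)
        kept = [h for h in qhits if categorize_hit(h).rank == best_rank]
        kept.sort(key=lambda h: (-h.bit_score, h.subject_id))
        out[qid] = kept
    return out


def _gap_columns(hit: AlignmentHit) -> int:
    if hit.gap_columns is not None:
        return hit.gap_columns
    # Imported 12-column hits only carry gap openings; approximating gap
    # columns by openings assumes single-base gaps.
    logger.debug("hit %s->%s: approximating gap columns by gap openings",
                 hit.query_id, hit.subject_id)
    return hit.gap_opens


def ortholog_hit_ratio(hits: Sequence[AlignmentHit]) -> OHRRecord | None:
    """Best OHR over a transcript's hits (``None`` for an empty hit list).

    Per hit the candidate ratio is (alignment columns − gap columns) divided
    by the full hit-sequence length, clamped to 1; the record keeps the
    maximal candidate and its subject.  All hits must share one query id.
    """
    if not hits:
        return None
    qids = {h.query_id for h in hits}
    if len(qids) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(qids)}")
    best_ohr, best_subject = -1.0, ""
    for hit in hits:
        ungapped = hit.aln_length - _gap_columns(hit)
        candidate = min(1.0, ungapped / hit.s_len)
        if candidate > best_ohr or (candidate == best_ohr
                                    and hit.subject_id < best_subject):
            best_ohr, best_subject = candidate, hit.subject_id
    return OHRRecord(transcript_id=qids.pop(), best_subject_id=best_subject,
                     ohr=best_ohr, n_hits_considered=len(hits))


def ohr_table(hits: Iterable[AlignmentHit],
              apply_best_category: bool = True) -> list[OHRRecord]:
    """Per-transcript best OHR over a whole hit list.

    When ``apply_best_category`` is set the four-tier best-hit filter is
    applied first, mirroring the annotation workflow.
    """
    if apply_best_category:
        grouped = best_hits_filter(hits)
    else:
        grouped = defaultdict(list)
        for h in hits:
            grouped[h.query_id].append(h)
    records = []
    for qid in sorted(grouped):
        rec = ortholog_hit_ratio(grouped[qid])
        if rec is not None:
            records.append(rec)
    return records


def ohr_summary(records: Sequence[OHRRecord]) -> dict[str, float]:
    """Mean OHR, fraction >= 0.7 and count at exactly 1.0."""
    if not records:
        return {"n": 0, "mean_ohr": 0.0, "fraction_ge_0.7": 0.0, "count_full_length": 0}
    values = [r.ohr for r in records]
    return {
        "n": len(records),
        "mean_ohr": sum(values) / len(values),
        "fraction_ge_0.7": sum(v >= 0.7 for v in values) / len(values),
        "count_full_length": sum(v == 1.0 for v in values),
    }


def assembly_stats(seqs: SequenceSet) -> AssemblyStats:
    """Count/mean/median/N50 over the sequence lengths of a set.

    N50 is the largest length L, attained by a sequence, such that
    sequences of length >= L together cover at least half the total bases.
    """
    if len(seqs) == 0:
        raise ValueError("cannot summarize an empty sequence set")
    lengths = sorted((len(rec) for rec in seqs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for length in lengths:
        acc += length
        if 2 * acc >= total:
            n50 = length
            break
    return AssemblyStats(
        n_sequences=len(lengths),
        total_bp=total,
        mean_length=total / len(lengths),
        median_length=float(statistics.median(lengths)),
        n50_length=n50,
    )
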
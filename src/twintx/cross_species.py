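"""Cross-species divergence analysis: reciprocal best hits and PDEG sets.

Homologous transcripts between two sibling-species assemblies are called by
reciprocal best hit (RBH) under stringent thresholds (e-value <= 1e-10 and
alignment overlap >= 90% of the query in each direction), a conservative
1:1 ortholog proxy chosen to avoid false positives between closely related
sets.  Transcripts with no qualifying cross-species hit at the looser
annotation threshold (e-value <= 1e-5) form the species-specific set —
Potential Differentially Expressed Genes (PDEGs).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AlignmentHit, SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "RBHPair",
    "DivergenceReport",
    "reciprocal_best_hits",
    "species_specific",
    "divergence_report",
]

RBH_EVALUE_MAX = 1e-10
RBH_MIN_OVERLAP_PCT = 90.0
PDEG_EVALUE_MAX = 1e-5
DIVERGENT_IDENTITY_CUTOFF = 97.0


@dataclass(frozen=True)
class RBHPair:
    """One reciprocal-best-hit ortholog pair.

    ``pct_identity`` is taken from the a->b hit; overlaps are the alignment
    length as a percentage of each sequence's own length.
    """

    id_a: str
    id_b: str
    pct_identity: float
    overlap_a: float
    overlap_b: float
    evalue_ab: float
    evalue_ba: float


@dataclass(frozen=True)
class DivergenceReport:
    n_pairs: int
    mean_identity: float
    min_identity: float
    max_identity: float
    median_identity: float
    divergent_pairs: tuple[RBHPair, ...]


def _best_per_query(hits: Iterable[AlignmentHit], evalue_max: float,
                    min_overlap_pct: float) -> dict[str, AlignmentHit]:
    """Best qualifying hit per query: max bit score, ties by identity then id."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.e_value > evalue_max or hit.query_overlap_pct < min_overlap_pct:
            continue
        cur = best.get(hit.query_id)
        if cur is None or (
            (-hit.bit_score, -hit.pct_identity, hit.subject_id)
            < (-cur.bit_score, -cur.pct_identity, cur.subject_id)
        ):
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[AlignmentHit],
    hits_ba: Iterable[AlignmentHit],
    evalue_max: float = RBH_EVALUE_MAX,
    min_overlap_pct: float = RBH_MIN_OVERLAP_PCT,
) -> list[RBHPair]:
    """Call RBH pairs from the two directional hit lists.

    A hit qualifies if its e-value is at or below ``evalue_max`` and it
    covers at least ``min_overlap_pct`` of its query; a pair is emitted iff
    each member is the other's best qualifying hit.  Enforcing the overlap
    on the query side in both directions means both overlaps of an emitted
    pair satisfy the threshold.
    """
    best_ab = _best_per_query(hits_ab, evalue_max, min_overlap_pct)
    best_ba = _best_per_query(hits_ba, evalue_max, min_overlap_pct)
    pairs: list[RBHPair] = []
    for id_a, hit_ab in sorted(best_ab.items()):
        id_b = hit_ab.subject_id
        hit_ba = best_ba.get(id_b)
        if hit_ba is None or hit_ba.subject_id != id_a:
            continue
        if abs(hit_ab.pct_identity - hit_ba.pct_identity) > 1.0:
            logger.warning(
                "RBH pair %s/%s: directional identities differ by more than "
                "1 point (%.2f vs %.2f)", id_a, id_b,
                hit_ab.pct_identity, hit_ba.pct_identity)
        pairs.append(RBHPair(
            id_a=id_a,
            id_b=id_b,
            pct_identity=hit_ab.pct_identity,
            overlap_a=hit_ab.query_overlap_pct,
            overlap_b=hit_ba.query_overlap_pct,
            evalue_ab=hit_ab.e_value,
            evalue_ba=hit_ba.e_value,
        ))
    return pairs


def species_specific(
    transcripts_a: SequenceSet,
    hits_ab: Iterable[AlignmentHit],
    evalue_max: float = PDEG_EVALUE_MAX,
) -> list[str]:
    """Ids of transcripts with no cross-species hit at the threshold (PDEGs)."""
    with_hit = {h.query_id for h in hits_ab if h.e_value <= evalue_max}
    return [rec.id for rec in transcripts_a if rec.id not in with_hit]


def divergence_report(
    pairs: Sequence[RBHPair],
    divergent_cutoff: float = DIVERGENT_IDENTITY_CUTOFF,
) -> DivergenceReport:
    """Identity summary over RBH pairs plus the divergent subset (< cutoff)."""
    if not pairs:
        raise ValueError("divergence report requires at least one RBH pair")
    idents = [p.pct_identity for p in pairs]
    divergent = tuple(p for p in pairs if p.pct_identity < divergent_cutoff)
    return DivergenceReport(
        n_pairs=len(pairs),
        mean_identity=sum(idents) / len(idents),
        min_identity=min(idents),
        max_identity=max(idents),
        median_identity=float(statistics.median(idents)),
        divergent_pairs=divergent,
    )
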
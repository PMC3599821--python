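"""Local pairwise alignment producing tabular-style hits.

The pipeline needs blastn-like behaviour — best local alignment per pair,
percent identity, e-value thresholds — without an external aligner binary.
Optimal affine-gap local alignment is delegated to
:class:`Bio.Align.PairwiseAligner`; this module adds strand handling,
hit construction, Karlin–Altschul e-values and a k-mer seeded all-vs-all
search so that whole transcript sets can be compared in one call.

Scoring convention: a gap of length L scores ``gap_open + (L-1)*gap_extend``
(the opening column carries the open penalty).  Percent identity is
``100 * matches / alignment_columns`` where columns include gap columns,
matching the tabular format's ``pident``.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

from Bio import Align

from .io_formats import AlignmentHit, SequenceRecord, SequenceSet

__all__ = [
    "ScoringScheme",
    "SearchConfig",
    "local_align",
    "evalue",
    "all_vs_all",
    "reverse_complement",
]

# Ungapped Karlin-Altschul lambda for +1/-2 scoring under uniform base
# composition has the closed form ln((3+sqrt(21))/2); K is the standard
# tabulated value for that scheme.  Fixed constants: only e-value *threshold*
# behaviour matters downstream, not absolute calibration of gapped statistics.
_DEFAULT_LAMBDA = math.log((3.0 + math.sqrt(21.0)) / 2.0)
_DEFAULT_K = 0.621

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring parameters plus Karlin–Altschul constants."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = _DEFAULT_LAMBDA
    karlin_k: float = _DEFAULT_K

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner(mode="local")
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        # Biopython charges open_gap_score for the first gap column and
        # extend_gap_score for each subsequent one, matching our convention.
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


@dataclass(frozen=True)
class SearchConfig:
    """Seeding and filtering parameters for the all-vs-all search."""

    kmer_size: int = 11
    min_seed_hits: int = 2
    evalue_cutoff: float = 1e-5
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.kmer_size < 4:
            raise ValueError("kmer_size must be >= 4")
        if self.min_seed_hits < 1:
            raise ValueError("min_seed_hits must be >= 1")


def evalue(raw_score: float, q_len: int, db_residues: int,
           scheme: ScoringScheme) -> tuple[float, float]:
    """Karlin–Altschul bit score and e-value for a raw alignment score.

    ``bit = (lambda*S - ln K) / ln 2`` and ``E = m*n*2^(-bit)``, computed in
    log space so large scores do not underflow through zero prematurely.
    """
    if raw_score <= 0:
        raise ValueError("raw score must be positive")
    if q_len < 1 or db_residues < 1:
        raise ValueError("search space dimensions must be positive")
    lam, k = scheme.karlin_lambda, scheme.karlin_k
    bit_score = (lam * raw_score - math.log(k)) / math.log(2.0)
    log_e = math.log(q_len) + math.log(db_residues) - bit_score * math.log(2.0)
    return bit_score, math.exp(log_e)


def _count_gap_opens(coords) -> tuple[int, int]:
    """(gap_opens, gap_columns) from a Biopython alignment coordinate array."""
    opens = 0
    columns = 0
    q, s = coords[0], coords[1]
    for i in range(1, len(q)):
        dq, ds = abs(int(q[i]) - int(q[i - 1])), abs(int(s[i]) - int(s[i - 1]))
        if dq == 0 and ds > 0:
            opens += 1
            columns += ds
        elif ds == 0 and dq > 0:
            opens += 1
            columns += dq
    return opens, columns


def _best_alignment(aligner: Align.PairwiseAligner, qseq: str, sseq: str):
    score = aligner.score(qseq, sseq)
    if score <= 0:
        return None, 0.0
    return aligner.align(qseq, sseq)[0], float(score)


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scheme: ScoringScheme | None = None,
    *,
    both_strands: bool = True,
    db_residues: int | None = None,
) -> AlignmentHit | None:
    """Optimal affine-gap local alignment of one query/subject pair.

    Returns ``None`` when the best local score is <= 0.  With
    ``both_strands`` the subject's reverse complement is also searched and
    the higher-scoring strand reported; a minus-strand hit carries
    ``s_start > s_end`` (1-based inclusive, standard tabular convention).
    ``db_residues`` defaults to the subject length (single-pair search space).
    """
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    qseq, sseq = query.residues, subject.residues

    fwd, fwd_score = _best_alignment(aligner, qseq, sseq)
    rev, rev_score = (None, 0.0)
    if both_strands:
        rev, rev_score = _best_alignment(aligner, qseq, reverse_complement(sseq))

    if fwd is None and rev is None:
        return None
    use_rev = rev is not None and (fwd is None or rev_score > fwd_score)
    aln, score = (rev, rev_score) if use_rev else (fwd, fwd_score)

    counts = aln.counts()
    matches, mismatches = counts.identities, counts.mismatches
    gap_opens, gap_columns = _count_gap_opens(aln.coordinates)
    columns = matches + mismatches + gap_columns

    q0, q1 = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    s0, s1 = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    s_len = len(subject)
    if use_rev:
        s_start, s_end = s_len - s0, s_len - s1 + 1
    else:
        s_start, s_end = s0 + 1, s1

    bit_score, e_val = evalue(score, len(query), db_residues or s_len, scheme)
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        pct_identity=100.0 * matches / columns,
        aln_length=columns,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=q0 + 1,
        q_end=q1,
        s_start=s_start,
        s_end=s_end,
        e_value=e_val,
        bit_score=bit_score,
        q_len=len(query),
        s_len=s_len,
        gap_columns=gap_columns,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def all_vs_all(
    queries: SequenceSet,
    subjects: SequenceSet,
    scheme: ScoringScheme | None = None,
    config: SearchConfig | None = None,
) -> list[AlignmentHit]:
    """K-mer seeded search of every query against every subject.

    A query/subject pair is aligned only if they share at least
    ``min_seed_hits`` distinct k-mers on either strand; the resulting hit is
    kept if its e-value (against the whole subject set as search space) is at
    or below the cutoff.  Output is sorted by (query_id, e-value ascending,
    bit score descending, subject_id) — one hit per pair, the single best
    local alignment.
    """
    scheme = scheme or ScoringScheme()
    config = config or SearchConfig()
    if len(queries) == 0 or len(subjects) == 0:
        raise ValueError("all_vs_all requires non-empty sequence sets")

    k = config.kmer_size
    db_residues = sum(len(rec) for rec in subjects)

    index: dict[str, set[str]] = defaultdict(set)  # kmer -> subject ids
    for rec in subjects:
        kmers = _kmer_set(rec.residues, k)
        if config.both_strands:
            kmers |= _kmer_set(reverse_complement(rec.residues), k)
        for km in kmers:
            index[km].add(rec.id)

    by_id = {rec.id: rec for rec in subjects}
    hits: list[AlignmentHit] = []
    for q in queries:
        shared: dict[str, int] = defaultdict(int)
        for km in _kmer_set(q.residues, k):
            for sid in index.get(km, ()):
                shared[sid] += 1
        for sid, n_shared in shared.items():
            if n_shared < config.min_seed_hits:
                continue
            hit = local_align(
                q, by_id[sid], scheme,
                both_strands=config.both_strands, db_residues=db_residues,
            )
            if hit is not None and hit.e_value <= config.evalue_cutoff:
                hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, h.e_value, -h.bit_score, h.subject_id))
    return hits
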
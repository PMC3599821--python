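"""CDS completeness classification by longest open reading frame.

Transcripts are classified into the classes a coding-sequence predictor
reports: *complete* (start and stop codon present), *n_fragment* (amino
end truncated: the reading frame runs off the 5' end of the transcript
without a start codon but ends at a stop), *c_fragment* (carboxyl end
truncated: starts at ATG but runs off the 3' end without a stop),
*both_fragment* (open frame spanning the whole transcript with neither),
and *none* (no open reading frame reaching the minimum length).

This is a deliberately simple longest-ORF criterion — no codon-usage or
self-trained coding model — sufficient to reproduce the class taxonomy on
sequences with planted coding structure.  Standard genetic code only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import SequenceRecord
from .pairwise_align import reverse_complement

__all__ = ["CDSClassification", "classify_cds", "class_counts"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

# chosen-candidate preference when equal-length ORFs compete
_CLASS_PRIORITY = {"complete": 0, "c_fragment": 1, "n_fragment": 2, "both_fragment": 3}


@dataclass(frozen=True)
class CDSClassification:
    """Completeness call for one transcript.

    ``frame`` is 1..3 for the forward strand, -1..-3 for the reverse;
    ``orf_start``/``orf_end`` are 0-based half-open coordinates on the
    transcript's forward strand (stop codon included when present).
    """

    transcript_id: str
    cds_class: str
    frame: int
    orf_start: int
    orf_end: int
    orf_length_bp: int


def _frame_candidates(seq: str, frame_offset: int, seq_len: int):
    """Candidate ORFs in one forward frame as (class, start, end) on ``seq``.

    A candidate stretch is a maximal codon run without an internal stop;
    its class depends on whether a start codon is available and whether a
    stop codon bounds it on the right within the transcript.  Stretches
    preceded by a stop that contain no ATG are not open reading frames in
    any class and are skipped.
    """
    codons = [seq[i:i + 3] for i in range(frame_offset, seq_len - 2, 3)]
    if not codons:
        return
    stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    boundaries = [-1] + stops + [len(codons)]
    for left, right in zip(boundaries[:-1], boundaries[1:]):
        # codon stretch (left, right): open codons are indices left+1 .. right-1
        first, last = left + 1, right - 1
        if first > last:
            continue  # empty stretch (adjacent stops)
        has_stop = right < len(codons)  # bounded on the right by a stop codon
        atg = next((i for i in range(first, last + 1)
                    if codons[i] == START_CODON), None)
        runs_off_5p = left == -1  # stretch touches the transcript 5' end
        if atg is not None and has_stop:
            yield ("complete", frame_offset + 3 * atg, frame_offset + 3 * (right + 1))
        elif atg is not None:
            yield ("c_fragment", frame_offset + 3 * atg, frame_offset + 3 * (last + 1))
        elif has_stop and runs_off_5p and first <= last:
            yield ("n_fragment", frame_offset + 3 * first, frame_offset + 3 * (right + 1))
        elif not has_stop and runs_off_5p and first <= last:
            yield ("both_fragment", frame_offset + 3 * first, frame_offset + 3 * (last + 1))


def classify_cds(seq: SequenceRecord, min_orf_bp: int = 300) -> CDSClassification:
    """Classify one transcript by its longest qualifying ORF over six frames.

    Among candidates of at least ``min_orf_bp``, the longest wins; equal
    lengths prefer the more complete class.  Coordinates of reverse-strand
    ORFs are mapped back to the forward strand.  Raises on sequences
    shorter than one codon.
    """
    residues = seq.residues
    n = len(residues)
    if n < 3:
        raise ValueError(f"transcript {seq.id}: shorter than one codon")

    candidates: list[tuple[str, int, int, int]] = []  # (class, start, end, frame)
    for offset in range(3):
        for cls, start, end in _frame_candidates(residues, offset, n):
            candidates.append((cls, start, end, offset + 1))
    rc = reverse_complement(residues)
    for offset in range(3):
        for cls, start, end in _frame_candidates(rc, offset, n):
            # map [start, end) on the reverse strand to forward coordinates
            candidates.append((cls, n - end, n - start, -(offset + 1)))

    best = None
    for cls, start, end, frame in candidates:
        length = end - start
        if length < min_orf_bp:
            continue
        key = (-length, _CLASS_PRIORITY[cls], abs(frame), frame < 0, start)
        if best is None or key < best[0]:
            best = (key, cls, start, end, frame)
    if best is None:
        return CDSClassification(transcript_id=seq.id, cds_class="none",
                                 frame=0, orf_start=0, orf_end=0, orf_length_bp=0)
    _, cls, start, end, frame = best
    return CDSClassification(transcript_id=seq.id, cds_class=cls, frame=frame,
                             orf_start=start, orf_end=end,
                             orf_length_bp=end - start)


def class_counts(classifications: Iterable[CDSClassification]) -> dict[str, int]:
    """Additive class tally: the four CDS classes, none, and totals."""
    counts = {"complete": 0, "n_fragment": 0, "c_fragment": 0,
              "both_fragment": 0, "none": 0}
    for c in classifications:
        counts[c.cds_class] += 1
    counts["total_predicted"] = sum(
        counts[k] for k in ("complete", "n_fragment", "c_fragment", "both_fragment"))
    counts["total"] = counts["total_predicted"] + counts["none"]
    return counts
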
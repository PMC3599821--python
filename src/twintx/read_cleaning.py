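"""Demultiplexing and cleaning of adapter-flanked raw reads.

The library layout is ``adapter A + 6 bp species barcode + 5' amplification
adapter + insert + 3' amplification adapter + adapter B``.  Cleaning
proceeds in three independent passes, each returning a report whose
per-bin counts sum exactly to its input count:

1. :func:`demultiplex_and_trim` — strip the adapters, read the barcode,
   bin each insert by species (or "unassigned").
2. :func:`filter_reads` — drop too-short and high-N inserts.
3. :func:`screen_rrna` — drop inserts with a qualifying local alignment to
   an rRNA reference set (bacterial-contamination screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import SequenceRecord, SequenceSet
from .pairwise_align import ScoringScheme, local_align
from .synthetic_data import ADAPTER_3P, ADAPTER_5P, ADAPTER_A, ADAPTER_B, BARCODES

__all__ = ["CleaningConfig", "CleaningReport", "demultiplex_and_trim",
           "filter_reads", "screen_rrna"]


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds for the cleaning passes.

    The short-read and N-ratio cutoffs are conventions for this library
    type, not universal constants: 100 bp matches the assembler's minimum
    contig length and 2% N is a customary pyrosequencing cutoff.  The rRNA
    screen thresholds (90% identity over >= 100 aligned bp) are likewise
    defaults, configurable.
    """

    adapter_a: str = ADAPTER_A
    adapter_b: str = ADAPTER_B
    adapter_5p: str = ADAPTER_5P
    adapter_3p: str = ADAPTER_3P
    barcodes: dict[str, str] = field(default_factory=lambda: dict(BARCODES))
    max_adapter_mismatches: int = 2
    min_length: int = 100
    max_n_fraction: float = 0.02
    rrna_reference: SequenceSet | None = None
    rrna_min_identity: float = 90.0
    rrna_min_overlap: int = 100
    min_partial_overlap: int = 8

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("at least one barcode is required")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError("all barcodes must have the same length")
        if not (0.0 <= self.max_n_fraction <= 1.0):
            raise ValueError("max_n_fraction must lie in [0, 1]")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes)))


@dataclass
class CleaningReport:
    """Per-bin removal counts for one cleaning pass."""

    input_count: int = 0
    adapter_only: int = 0
    unassigned_barcode: int = 0
    removed_short: int = 0
    removed_high_n: int = 0
    removed_rrna: int = 0
    output_counts: dict[str, int] = field(default_factory=dict)

    @property
    def output_total(self) -> int:
        return sum(self.output_counts.values())

    @property
    def removed_total(self) -> int:
        return (self.adapter_only + self.unassigned_barcode + self.removed_short
                + self.removed_high_n + self.removed_rrna)

    def check_conservation(self) -> None:
        if self.removed_total + self.output_total != self.input_count:
            raise AssertionError("cleaning report does not conserve read counts")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _strip_3p(seq: str, adapter: str, max_mm: int, min_partial: int) -> str:
    """Remove a full or partial (prefix-of-adapter) occurrence at the 3' end.

    A full suffix match tolerates ``max_mm`` mismatches; a truncated adapter
    is recognized only as an exact prefix of length >= ``min_partial`` at
    the extreme end of the read.
    """
    n = len(adapter)
    if len(seq) >= n and _hamming(seq[-n:], adapter) <= max_mm:
        return seq[:-n]
    for k in range(min(n - 1, len(seq)), min_partial - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[:-k]
    return seq


def demultiplex_and_trim(
    reads: SequenceSet, config: CleaningConfig | None = None,
) -> tuple[dict[str, SequenceSet], CleaningReport]:
    """Strip adapters/barcodes and bin inserts by species.

    Adapter A must anchor at position 0 within the mismatch budget; the
    following barcode selects the species bin (exact match, else the read
    goes to "unassigned").  The 5' amplification adapter is stripped when
    present after the barcode; the outer B adapter and 3' amplification
    adapter are stripped from the 3' end, tolerating partial (truncated)
    occurrences.  Reads whose insert vanishes entirely are counted as
    adapter-only.  No read is ever silently dropped: every input lands in a
    species bin, "unassigned", or a removal counter.
    """
    config = config or CleaningConfig()
    report = CleaningReport(input_count=len(reads))
    bins: dict[str, list[SequenceRecord]] = {sp: [] for sp in config.barcodes.values()}
    bins["unassigned"] = []
    la, lb = len(config.adapter_a), config.barcode_length
    l5 = len(config.adapter_5p)
    mm = config.max_adapter_mismatches

    for rec in reads:
        seq = rec.residues
        if len(seq) < la + lb or _hamming(seq[:la], config.adapter_a) > mm:
            report.unassigned_barcode += 1
            bins["unassigned"].append(rec)
            continue
        barcode = seq[la : la + lb]
        species = config.barcodes.get(barcode)
        if species is None:
            report.unassigned_barcode += 1
            bins["unassigned"].append(rec)
            continue
        insert = seq[la + lb:]
        if len(insert) >= l5 and _hamming(insert[:l5], config.adapter_5p) <= mm:
            insert = insert[l5:]
        insert = _strip_3p(insert, config.adapter_b, mm, config.min_partial_overlap)
        insert = _strip_3p(insert, config.adapter_3p, mm, config.min_partial_overlap)
        if not insert:
            report.adapter_only += 1
            continue
        bins[species].append(SequenceRecord(
            id=rec.id, residues=insert, description=rec.description))

    out = {sp: SequenceSet(label=sp, records=recs) for sp, recs in bins.items()}
    report.output_counts = {sp: len(recs) for sp, recs in bins.items()
                            if sp != "unassigned"}
    # unassigned reads are already tallied as removals, not outputs
    report.check_conservation()
    return out, report


def filter_reads(
    reads: SequenceSet, config: CleaningConfig | None = None,
) -> tuple[SequenceSet, CleaningReport]:
    """Drop reads shorter than ``min_length`` or with too many Ns.

    Order of survivors is preserved; the pass is idempotent.
    """
    config = config or CleaningConfig()
    report = CleaningReport(input_count=len(reads))
    kept: list[SequenceRecord] = []
    for rec in reads:
        if len(rec) < config.min_length:
            report.removed_short += 1
        elif rec.residues.count("N") / len(rec) > config.max_n_fraction:
            report.removed_high_n += 1
        else:
            kept.append(rec)
    report.output_counts = {reads.label: len(kept)}
    report.check_conservation()
    return SequenceSet(label=reads.label, records=kept), report


def screen_rrna(
    reads: SequenceSet, config: CleaningConfig | None = None,
) -> tuple[SequenceSet, CleaningReport]:
    """Remove reads with a qualifying local alignment to the rRNA reference.

    A read is contaminant if any reference alignment reaches at least
    ``rrna_min_identity`` percent identity over at least
    ``rrna_min_overlap`` aligned columns.  Without a reference set this is
    an identity pass-through.
    """
    config = config or CleaningConfig()
    report = CleaningReport(input_count=len(reads))
    if config.rrna_reference is None or len(config.rrna_reference) == 0:
        report.output_counts = {reads.label: len(reads)}
        report.check_conservation()
        return reads, report
    scheme = ScoringScheme()
    kept: list[SequenceRecord] = []
    for rec in reads:
        contaminated = False
        for ref in config.rrna_reference:
            hit = local_align(rec, ref, scheme)
            if (hit is not None
                    and hit.pct_identity >= config.rrna_min_identity
                    and hit.aln_length >= config.rrna_min_overlap):
                contaminated = True
                break
        if contaminated:
            report.removed_rrna += 1
        else:
            kept.append(rec)
    report.output_counts = {reads.label: len(kept)}
    report.check_conservation()
    return SequenceSet(label=reads.label, records=kept), report
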
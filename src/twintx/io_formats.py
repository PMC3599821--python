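"""Readers and writers for the formats the pipeline consumes and emits.

Sequence sets are plain FASTA/FASTQ (phred+33); alignment hits travel in the
standard 12-column tab-separated format (qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore); reports are TSV with a
header row.  All coordinates are 1-based inclusive *on disk* and converted at
the file boundary; in memory the package works 0-based half-open.

The 12-column format does not carry full sequence lengths, which the
ortholog-hit-ratio and overlap computations need, so ``read_tabular_hits``
takes the query/subject length maps (normally derived from the FASTA sets)
as explicit arguments.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "SequenceRecord",
    "SequenceSet",
    "AlignmentHit",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "write_table",
]

_VALID_RESIDUES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA/FASTQ entry.

    ``residues`` is uppercase over {A,C,G,T,N}; ``quality`` is a tuple of
    phred integers of the same length, or ``None`` for FASTA input.
    """

    id: str
    residues: str
    description: str = ""
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.residues):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered, id-unique collection of sequence records."""

    label: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in set {self.label!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def lengths(self) -> dict[str, int]:
        return {rec.id: len(rec) for rec in self.records}


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local-alignment hit with 12-column tabular semantics.

    Coordinates are 1-based inclusive as in the tabular format; a
    reverse-strand subject hit is encoded by ``s_start > s_end``.  ``q_len``
    and ``s_len`` (full sequence lengths) are carried alongside because the
    12-column format omits them.  ``gap_columns`` is the true number of gap
    columns when the hit came from the internal aligner and ``None`` for
    imported hits (consumers then fall back to ``gap_opens``).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    q_len: int
    s_len: int
    gap_columns: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if self.q_len < 1 or self.s_len < 1:
            raise ValueError("q_len and s_len must be >= 1")
        gaps = self.gap_columns if self.gap_columns is not None else self.gap_opens
        if self.mismatches + gaps > self.aln_length:
            raise ValueError("mismatches + gap columns exceed alignment length")

    @property
    def subject_reversed(self) -> bool:
        return self.s_start > self.s_end

    @property
    def query_overlap_pct(self) -> float:
        """Alignment length as a percentage of the full query length."""
        return 100.0 * self.aln_length / self.q_len


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _clean_residues(raw: str, rec_id: str, offset_hint: int) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"record {rec_id!r}: non-IUPAC character {seq[pos]!r} at position "
            f"{offset_hint + pos + 1}"
        )
    return seq


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA or FASTQ file (dialect detected from the first character).

    Residues are uppercased and U mapped to T; multi-line FASTA sequences are
    concatenated; FASTQ qualities are decoded as phred+33.  Raises
    ``ValueError`` on an empty file, a duplicate id, or a character outside
    {A,C,G,T,N,U} (case-insensitive).
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.read(1)
        if not first:
            raise ValueError(f"{path}: no records")
        fh.seek(0)
        if first == ">":
            records = list(_parse_fasta(fh))
        elif first == "@":
            records = list(_parse_fastq(fh, str(path)))
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
    if not records:
        raise ValueError(f"{path}: no records")
    label = path.name
    for suffix in (".gz", ".fa", ".fasta", ".fq", ".fastq", ".fna"):
        if label.endswith(suffix):
            label = label[: -len(suffix)]
    return SequenceSet(label=label, records=records)


def _parse_fasta(fh: Iterable[str]) -> Iterator[SequenceRecord]:
    header: str | None = None
    chunks: list[str] = []
    for line in fh:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if header is not None:
                yield _make_fasta_record(header, chunks)
            header = line[1:]
            chunks = []
        elif line:
            chunks.append(line.strip())
    if header is not None:
        yield _make_fasta_record(header, chunks)


def _make_fasta_record(header: str, chunks: list[str]) -> SequenceRecord:
    fields = header.split(None, 1)
    rec_id = fields[0] if fields else ""
    desc = fields[1] if len(fields) > 1 else ""
    seq = _clean_residues("".join(chunks), rec_id, 0)
    return SequenceRecord(id=rec_id, residues=seq, description=desc)


def _parse_fastq(fh: Iterable[str], name: str) -> Iterator[SequenceRecord]:
    lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 and lines[-1] == "":
        lines = lines[:-1]
    if len(lines) % 4:
        raise ValueError(f"{name}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq_line, plus, qual_line = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{name}: malformed FASTQ record at line {i + 1}")
        fields = head[1:].split(None, 1)
        rec_id = fields[0] if fields else ""
        desc = fields[1] if len(fields) > 1 else ""
        seq = _clean_residues(seq_line, rec_id, 0)
        qual = tuple(ord(c) - 33 for c in qual_line)
        yield SequenceRecord(id=rec_id, residues=seq, description=desc, quality=qual)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> Path:
    """Write a SequenceSet as multi-line FASTA; returns the path."""
    path = Path(path)
    with open(path, "wt") as fh:
        for rec in seqs:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
    return path


_HIT_COLUMNS = 12


def read_tabular_hits(
    path: str | Path,
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
) -> list[AlignmentHit]:
    """Parse a 12-column tabular hit file, attaching full sequence lengths.

    Lines naming a query/subject absent from the length maps are an error
    (hits are meaningless without the lengths the downstream ratios divide
    by).  Imported hits have ``gap_columns=None``.
    """
    hits: list[AlignmentHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < _HIT_COLUMNS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_HIT_COLUMNS} tab-separated "
                    f"fields, got {len(parts)}"
                )
            qid, sid = parts[0], parts[1]
            if qid not in query_lengths:
                raise ValueError(f"{path}: line {lineno}: unknown query id {qid!r}")
            if sid not in subject_lengths:
                raise ValueError(f"{path}: line {lineno}: unknown subject id {sid!r}")
            try:
                hit = AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                    q_len=query_lengths[qid],
                    s_len=subject_lengths[sid],
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_tabular_hits(hits: Sequence[AlignmentHit], path: str | Path) -> Path:
    """Write hits in the standard 12-column tabular layout (no header)."""
    path = Path(path)
    with open(path, "wt") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        _format_evalue(h.e_value),
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
    return path


def _format_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    if e >= 0.001:
        return f"{e:.3g}"
    return f"{e:.2e}"


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                fieldnames: Sequence[str] | None = None) -> Path:
    """Write flat records as a TSV with a header line.

    All rows must share the same field names; floats are rendered with 4
    decimal places; row order is preserved.  ``fieldnames`` must be given for
    an empty row list (to emit a header-only file).
    """
    path = Path(path)
    if rows:
        fields = list(rows[0].keys())
        for i, row in enumerate(rows):
            if list(row.keys()) != fields:
                raise ValueError(f"row {i} has field names {list(row.keys())}, expected {fields}")
        if fieldnames is not None and list(fieldnames) != fields:
            raise ValueError("declared fieldnames disagree with row fields")
    else:
        if fieldnames is None:
            raise ValueError("empty row list requires explicit fieldnames")
        fields = list(fieldnames)
    with open(path, "wt") as fh:
        fh.write("\t".join(fields) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row[f]) for f in fields) + "\n")
    return path


def _format_cell(value: object) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isinf(value):
            return "inf"
        return f"{value:.4f}"
    return str(value)


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read back a TSV written by :func:`write_table` (all values as strings)."""
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n")]
    if not lines:
        raise ValueError(f"{path}: empty table")
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"), strict=True)) for ln in lines[1:]]
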
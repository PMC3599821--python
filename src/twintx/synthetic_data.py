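"""Twin-transcriptome simulator with recorded ground truth.

Emulates the data a cross-species de novo assembly comparison sees: two
transcript sets descended from a common ancestor pool at a controlled
per-site divergence, plus species-specific transcripts with no homolog,
partial-length transcripts covering known fractions of full-length
references, GO annotations with optionally planted enrichment, and raw
pyrosequencing-style reads carrying the library's adapter/barcode structure
and homopolymer run-lengthening errors.

Divergence semantics: ``divergence`` is the expected *pairwise* per-site
substitution divergence between the two descendant copies; each copy is
mutated at ``divergence/2`` relative to the ancestor so that e.g. 0.02
yields a mean alignment identity near 98%.  ``indel_rate`` is split the
same way.  ``realized_identity`` recorded in the truth table is the percent
identity of the optimal global alignment of the two descendant copies
(computed at generation time), i.e. what an aligner can actually observe,
not the raw planted edit count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .io_formats import SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "ADAPTER_A",
    "ADAPTER_B",
    "ADAPTER_5P",
    "ADAPTER_3P",
    "BARCODES",
    "generate_twin_transcriptomes",
    "generate_reads",
    "generate_go_annotations",
]

# 454 library structure: titanium adapters A/B at the outer ends, a 6 bp
# species barcode, then amplification adapters flanking the cDNA insert.
ADAPTER_A = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
ADAPTER_B = "CTGAGACTGCCAAGGCACACAGGGGATAGG"
ADAPTER_5P = "GACCTTGGCTGTCACTC"
ADAPTER_3P = "TCGCAGTGAGTGACAGGCCA"
BARCODES = {"ATCAGC": "nubilalis", "CACACG": "scapulalis"}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the twin-transcriptome simulation (all rates per site)."""

    n_orthologs: int = 200
    n_specific_a: int = 50
    n_specific_b: int = 50
    length_range: tuple[int, int] = (300, 900)
    divergence: float = 0.02
    indel_rate: float = 0.002
    fragment_fractions: tuple[float, ...] = (1.0,)
    reads_per_transcript: int = 3
    read_length_range: tuple[int, int] = (150, 350)
    homopolymer_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orthologs < 0 or self.n_specific_a < 0 or self.n_specific_b < 0:
            raise ValueError("transcript counts must be non-negative")
        for lo, hi in (self.length_range, self.read_length_range):
            if lo > hi or lo < 1:
                raise ValueError("length ranges must satisfy 1 <= min <= max")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must lie in [0, 1)")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must lie in [0, 1)")
        if not all(0.0 < f <= 1.0 for f in self.fragment_fractions):
            raise ValueError("fragment fractions must lie in (0, 1]")
        if not (0.0 <= self.homopolymer_error_rate <= 1.0):
            raise ValueError("homopolymer_error_rate must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth of one simulation run.

    ``ortholog_pairs`` holds (id_a, id_b, realized_identity); every
    transcript id appears in exactly one of the ortholog or specific sets.
    ``coverage_fraction`` maps transcript id to its realized fraction of the
    ancestor length (exactly ``truncated_len / ancestor_len``).
    ``read_origin`` maps read id to (transcript_id, species, barcode,
    planted_error).  ``go_truth`` maps term -> "none" | "a" | "b".
    """

    ortholog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    specific_a: list[str] = field(default_factory=list)
    specific_b: list[str] = field(default_factory=list)
    coverage_fraction: dict[str, float] = field(default_factory=dict)
    read_origin: dict[str, tuple[str, str, str, bool]] = field(default_factory=dict)
    go_truth: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float) -> str:
    """Apply iid per-site substitutions and single-base indels.

    Substitutions pick uniformly among the 3 alternative bases; an indel is
    an insertion or deletion with equal probability.
    """
    out: list[str] = []
    for base in seq:
        r = rng.random()
        if indel_rate and r < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append("".join(_BASES[rng.integers(0, 4, size=1)]))  # insertion before
            out.append(base)
            continue
        if sub_rate and r < indel_rate + sub_rate:
            alternatives = [b for b in "ACGT" if b != base]
            out.append(alternatives[rng.integers(0, 3)])
        else:
            out.append(base)
    return "".join(out)


def _truncate(rng: np.random.Generator, seq: str, fraction: float) -> tuple[str, float]:
    """Truncate to ``fraction`` of the length from a random end.

    Returns the fragment and the realized fraction (kept_len / full_len).
    """
    if fraction >= 1.0:
        return seq, 1.0
    keep = max(1, round(fraction * len(seq)))
    if rng.random() < 0.5:
        frag = seq[:keep]  # 3' truncation
    else:
        frag = seq[len(seq) - keep:]  # 5' truncation
    return frag, keep / len(seq)


_global_aligner = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=-2,
    open_gap_score=-5, extend_gap_score=-2,
)


def _global_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment (gap columns count)."""
    aln = _global_aligner.align(a, b)[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    return 100.0 * c.identities / columns


def generate_twin_transcriptomes(
    config: SimulationConfig,
) -> tuple[SequenceSet, SequenceSet, SequenceSet, TruthTable]:
    """Simulate two descendant transcript sets plus full-length references.

    Each ortholog: one ancestor drawn uniformly over {A,C,G,T}, two copies
    independently mutated at half the pairwise divergence/indel rates, each
    optionally truncated to a drawn fragment fraction.  Species-specific
    transcripts are unrelated random sequences.  The reference set contains
    the full-length ancestors (the "hit sequences" for completeness
    assessment).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    recs_a: list[SequenceRecord] = []
    recs_b: list[SequenceRecord] = []
    refs: list[SequenceRecord] = []
    lo, hi = config.length_range
    sub_half = config.divergence / 2.0
    indel_half = config.indel_rate / 2.0

    for i in range(config.n_orthologs):
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq(rng, length)
        ref_id = f"ref{i:04d}"
        refs.append(SequenceRecord(id=ref_id, residues=ancestor,
                                   description="ancestor"))
        copy_a = _mutate(rng, ancestor, sub_half, indel_half)
        copy_b = _mutate(rng, ancestor, sub_half, indel_half)
        identity = _global_identity(copy_a, copy_b)

        frac_a = float(config.fragment_fractions[
            rng.integers(0, len(config.fragment_fractions))])
        frac_b = float(config.fragment_fractions[
            rng.integers(0, len(config.fragment_fractions))])
        frag_a, real_a = _truncate(rng, copy_a, frac_a)
        frag_b, real_b = _truncate(rng, copy_b, frac_b)

        id_a, id_b = f"a{i:04d}", f"b{i:04d}"
        recs_a.append(SequenceRecord(id=id_a, residues=frag_a,
                                     description=f"ortholog_of={ref_id}"))
        recs_b.append(SequenceRecord(id=id_b, residues=frag_b,
                                     description=f"ortholog_of={ref_id}"))
        truth.ortholog_pairs.append((id_a, id_b, identity))
        truth.coverage_fraction[id_a] = real_a
        truth.coverage_fraction[id_b] = real_b

    for i in range(config.n_specific_a):
        length = int(rng.integers(lo, hi + 1))
        rec_id = f"aspec{i:04d}"
        recs_a.append(SequenceRecord(id=rec_id, residues=_random_seq(rng, length),
                                     description="species_specific"))
        truth.specific_a.append(rec_id)
        truth.coverage_fraction[rec_id] = 1.0
    for i in range(config.n_specific_b):
        length = int(rng.integers(lo, hi + 1))
        rec_id = f"bspec{i:04d}"
        recs_b.append(SequenceRecord(id=rec_id, residues=_random_seq(rng, length),
                                     description="species_specific"))
        truth.specific_b.append(rec_id)
        truth.coverage_fraction[rec_id] = 1.0

    set_a = SequenceSet(label="species_a", records=recs_a)
    set_b = SequenceSet(label="species_b", records=recs_b)
    ref_set = SequenceSet(label="references", records=refs)
    return set_a, set_b, ref_set, truth


def _homopolymer_runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal runs of length >= 2 as (start, length, base), N excluded."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= 2 and seq[i] != "N":
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def generate_reads(
    transcripts: SequenceSet,
    species_barcode: str,
    config: SimulationConfig,
    truth: TruthTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SequenceSet, TruthTable]:
    """Sample adapter-flanked reads from a transcript set.

    Each read is ``ADAPTER_A + barcode + ADAPTER_5P + insert + ADAPTER_3P +
    ADAPTER_B`` where the insert is a random substring of a transcript with
    length drawn uniformly from ``read_length_range``.  With probability
    ``homopolymer_error_rate`` one existing homopolymer run (>= 2 bp) inside
    the insert is lengthened by 1–3 bp, emulating the dominant
    pyrosequencing error mode; the planted-error flag is recorded.
    Transcripts shorter than the minimum insert length are skipped with a
    logged warning.
    """
    if len(species_barcode) != 6:
        raise ValueError("species barcode must be 6 bp")
    truth = truth if truth is not None else TruthTable()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    species = BARCODES.get(species_barcode, transcripts.label)
    lo, hi = config.read_length_range
    reads: list[SequenceRecord] = []
    counter = len(truth.read_origin)
    for rec in transcripts:
        if len(rec) < lo:
            logger.warning("transcript %s (%d bp) shorter than minimum insert "
                           "length %d; skipped", rec.id, len(rec), lo)
            continue
        for _ in range(config.reads_per_transcript):
            ins_len = int(rng.integers(lo, min(hi, len(rec)) + 1))
            start = int(rng.integers(0, len(rec) - ins_len + 1))
            insert = rec.residues[start : start + ins_len]
            planted = False
            if config.homopolymer_error_rate and (
                    rng.random() < config.homopolymer_error_rate):
                runs = _homopolymer_runs(insert)
                if runs:
                    pos, run_len, base = runs[rng.integers(0, len(runs))]
                    extra = int(rng.integers(1, 4))
                    insert = insert[:pos] + base * (run_len + extra) + insert[pos + run_len:]
                    planted = True
            read_id = f"read{counter:06d}"
            counter += 1
            reads.append(SequenceRecord(
                id=read_id,
                residues=ADAPTER_A + species_barcode + ADAPTER_5P + insert
                + ADAPTER_3P + ADAPTER_B,
                description=f"origin={rec.id}",
            ))
            truth.read_origin[read_id] = (rec.id, species, species_barcode, planted)
    return SequenceSet(label=f"reads_{species}", records=reads), truth


def generate_go_annotations(
    set_a: SequenceSet,
    set_b: SequenceSet,
    truth: TruthTable,
    n_terms: int,
    enriched_terms: list[tuple[str, str, float]] | None = None,
    seed: int = 0,
) -> tuple[dict[str, set[str]], TruthTable]:
    """Assign GO terms to transcripts, optionally planting enrichment.

    Background terms are assigned to every transcript independently at a
    per-term base frequency drawn uniformly from [0.10, 0.40] (large enough
    that the downstream 2x2 tables are non-degenerate and the exact test
    approximately calibrated).  Each entry of
    ``enriched_terms`` is (term, "a"|"b", odds multiplier): that term's odds
    of assignment are multiplied for the designated species' *specific*
    transcripts.  Returns the transcript->terms table and updates
    ``truth.go_truth`` with the planted direction.
    """
    enriched_terms = enriched_terms or []
    for term, species, mult in enriched_terms:
        if species not in ("a", "b"):
            raise ValueError(f"enriched term {term}: species must be 'a' or 'b'")
        if mult <= 0:
            raise ValueError(f"enriched term {term}: multiplier must be positive")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    enriched_map = {term: (species, mult) for term, species, mult in enriched_terms}
    for term in terms:
        truth.go_truth[term] = enriched_map.get(term, ("none", 1.0))[0]
    specific = {"a": set(truth.specific_a), "b": set(truth.specific_b)}

    table: dict[str, set[str]] = {}
    base_freqs = rng.uniform(0.10, 0.40, size=n_terms)
    members = [(rec.id, "a") for rec in set_a] + [(rec.id, "b") for rec in set_b]
    for term, p in zip(terms, base_freqs):
        boost_species, mult = enriched_map.get(term, (None, 1.0))
        odds = p / (1.0 - p)
        p_boost = (odds * mult) / (1.0 + odds * mult)
        for tid, species in members:
            prob = p_boost if (boost_species == species and tid in specific[species]) else p
            if rng.random() < prob:
                table.setdefault(tid, set()).add(term)
    return table, truth


_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
)


class PlantedCDS:
    """A transcript with one dominant planted coding sequence.

    Layout: 5'UTR + spacer + ATG + ``n_codons`` sense codons + stop +
    spacer + 3'UTR.  The body avoids in-frame ATG and stop codons, and the
    construction rejection-samples until no open stretch in any other
    reading frame (either strand) reaches 280 bp, so the planted ORF — and
    each of its truncation variants below, all >= 300 bp — is guaranteed to
    be the longest open reading frame in the transcript.  Used to validate
    the completeness classifier against known structure.
    """

    N_CODONS = 120
    UTR = 30

    def __init__(self, rng: np.random.Generator):
        while True:
            seq = self._draw(rng)
            stretches = self._open_stretch_lengths(seq)
            long = [x for x in stretches if x >= 3 * self.N_CODONS]
            rest = [x for x in stretches if x < 3 * self.N_CODONS]
            if len(long) == 1 and (not rest or max(rest) < 280):
                break
        self.sequence = seq
        self.atg = self.UTR + 1
        self.stop_start = self.atg + 3 + 3 * self.N_CODONS

    def _draw(self, rng: np.random.Generator) -> str:
        def sense(n_bases: int) -> str:
            n = (n_bases + 2) // 3
            s = "".join(_SENSE_CODONS[i]
                        for i in rng.integers(0, len(_SENSE_CODONS), size=n))
            return s[:n_bases]

        body = "".join(_SENSE_CODONS[i] for i in
                       rng.integers(0, len(_SENSE_CODONS), size=self.N_CODONS))
        stop = _STOPS[rng.integers(0, 3)]
        return (sense(self.UTR) + "T" + "ATG" + body + stop + "T"
                + sense(self.UTR))

    @staticmethod
    def _open_stretch_lengths(seq: str) -> list[int]:
        lengths = []
        for strand in (seq, seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]):
            for offset in range(3):
                run = 0
                for i in range(offset, len(strand) - 2, 3):
                    if strand[i:i + 3] in _STOPS:
                        lengths.append(run * 3)
                        run = 0
                    else:
                        run += 1
                lengths.append(run * 3)
        return lengths

    def variant(self, kind: str) -> str:
        """Truncation with known completeness class ('complete',
        'c_fragment', 'n_fragment' or 'both_fragment')."""
        seq = self.sequence
        if kind == "complete":
            return seq
        if kind == "c_fragment":
            return seq[: self.stop_start]        # stop codon and 3' UTR gone
        if kind == "n_fragment":
            return seq[self.atg + 30:]           # 5' UTR, ATG and 10 codons gone
        if kind == "both_fragment":
            return seq[self.atg + 3 : self.stop_start]  # bare body
        raise ValueError(f"unknown variant {kind!r}")


def write_truth_table(truth: TruthTable, path) -> None:
    """Serialize the truth table as sectioned TSV (one block per field)."""
    from pathlib import Path

    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("#ortholog_pairs\tid_a\tid_b\trealized_identity\n")
        for id_a, id_b, ident in truth.ortholog_pairs:
            fh.write(f"pair\t{id_a}\t{id_b}\t{ident:.4f}\n")
        for sid in truth.specific_a:
            fh.write(f"specific_a\t{sid}\n")
        for sid in truth.specific_b:
            fh.write(f"specific_b\t{sid}\n")
        for tid, frac in truth.coverage_fraction.items():
            fh.write(f"coverage\t{tid}\t{frac:.6f}\n")
        for rid, (tid, species, barcode, planted) in truth.read_origin.items():
            fh.write(f"read\t{rid}\t{tid}\t{species}\t{barcode}\t{int(planted)}\n")
        for term, direction in truth.go_truth.items():
            fh.write(f"go\t{term}\t{direction}\n")
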
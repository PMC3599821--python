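"""Longest-homopolymer profiling of a sequence set.

Pyrosequencing's dominant error mode is mis-called homopolymer run lengths,
so a cheap QC on a read or transcript set is the distribution, per
nucleotide, of each sequence's *longest* run of that nucleotide.  A
homopolymer here is a run of at least two identical consecutive bases; N
breaks runs and never extends one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import SequenceRecord, SequenceSet

__all__ = ["HomopolymerProfile", "longest_runs", "profile"]

NUCLEOTIDES = "ACGT"


def longest_runs(seq: SequenceRecord | str) -> dict[str, int]:
    """Length of the longest maximal run of each nucleotide in one sequence.

    Returns 1 for a base occurring only in isolation and 0 for an absent
    base, so the operation is total; the profile layer applies the >= 2
    homopolymer cutoff.  Raises on an empty sequence.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    if not residues:
        raise ValueError("cannot profile an empty sequence")
    best = dict.fromkeys(NUCLEOTIDES, 0)
    run_base, run_len = "", 0
    for base in residues:
        if base == run_base:
            run_len += 1
        else:
            run_base, run_len = base, 1
        if base in best and run_len > best[base]:
            best[base] = run_len
    return best


@dataclass
class HomopolymerProfile:
    """Per-nucleotide longest-run histograms over a sequence set.

    ``histograms[b][L]`` counts sequences whose longest run of base ``b``
    has length ``L`` (only runs >= 2 are tallied); ``mean_longest[b]``
    averages over the sequences contributing such a run; ``global_max`` is
    the longest run of any base anywhere in the set.
    """

    n_sequences: int
    histograms: dict[str, Counter] = field(default_factory=dict)
    mean_longest: dict[str, float] = field(default_factory=dict)
    global_max: int = 0

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for base in NUCLEOTIDES:
            for length in sorted(self.histograms[base]):
                rows.append({"nucleotide": base, "run_length": length,
                             "count": self.histograms[base][length]})
        return rows


def profile(seqs: SequenceSet) -> HomopolymerProfile:
    """Aggregate longest-run statistics over a non-empty sequence set."""
    if len(seqs) == 0:
        raise ValueError("cannot profile an empty sequence set")
    hists: dict[str, Counter] = {b: Counter() for b in NUCLEOTIDES}
    for rec in seqs:
        runs = longest_runs(rec)
        for base, length in runs.items():
            if length >= 2:
                hists[base][length] += 1
    means = {}
    global_max = 0
    for base in NUCLEOTIDES:
        total = sum(hists[base].values())
        means[base] = (
            sum(length * n for length, n in hists[base].items()) / total
            if total else 0.0
        )
        if hists[base]:
            global_max = max(global_max, max(hists[base]))
    return HomopolymerProfile(
        n_sequences=len(seqs), histograms=hists,
        mean_longest=means, global_max=global_max,
    )
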
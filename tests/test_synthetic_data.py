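"""Simulator ground truth: determinism, divergence calibration, reads, GO."""

import copy

import numpy as np
import pytest
from scipy import stats

from twintx.pairwise_align import ScoringScheme, local_align
from twintx.synthetic_data import (
    ADAPTER_3P,
    ADAPTER_5P,
    ADAPTER_A,
    ADAPTER_B,
    SimulationConfig,
    generate_go_annotations,
    generate_reads,
    generate_twin_transcriptomes,
)


def _cfg(**kw):
    return SimulationConfig(**{**dict(n_orthologs=10, n_specific_a=3,
                                      n_specific_b=3, seed=1), **kw})


class TestTwinTranscriptomes:
    def test_same_seed_reproduces_byte_identical_output(self):
        out1 = generate_twin_transcriptomes(_cfg())
        out2 = generate_twin_transcriptomes(_cfg())
        for s1, s2 in zip(out1[:3], out2[:3]):
            assert [(r.id, r.residues) for r in s1] == [
                (r.id, r.residues) for r in s2]
        assert out1[3].ortholog_pairs == out2[3].ortholog_pairs

    def test_zero_mutation_orthologs_are_identical(self):
        cfg = _cfg(divergence=0.0, indel_rate=0.0, fragment_fractions=(1.0,))
        set_a, set_b, refs, truth = generate_twin_transcriptomes(cfg)
        for id_a, id_b, identity in truth.ortholog_pairs:
            assert identity == 100.0
            assert set_a[id_a].residues == set_b[id_b].residues
            assert set_a[id_a].residues == refs[f"ref{id_a[1:]}"].residues

    def test_specific_only_configuration(self):
        cfg = SimulationConfig(n_orthologs=0, n_specific_a=5, n_specific_b=0,
                               seed=2)
        set_a, set_b, refs, truth = generate_twin_transcriptomes(cfg)
        assert len(set_a) == 5 and len(set_b) == 0 and len(refs) == 0
        assert truth.ortholog_pairs == []
        assert len(truth.specific_a) == 5

    def test_every_id_in_exactly_one_truth_partition(self, small_twin):
        set_a, set_b, _, truth = small_twin
        ortho = {a for a, _, _ in truth.ortholog_pairs} | {
            b for _, b, _ in truth.ortholog_pairs}
        specific = set(truth.specific_a) | set(truth.specific_b)
        all_ids = set(set_a.ids) | set(set_b.ids)
        assert ortho | specific == all_ids
        assert not ortho & specific

    def test_mean_identity_within_binomial_interval(self):
        """200 pairs at pairwise divergence 0.02: the aggregate identity sits
        inside the exact binomial 99% interval around 98% (site count =
        total alignment columns)."""
        cfg = SimulationConfig(n_orthologs=200, n_specific_a=0, n_specific_b=0,
                               divergence=0.02, indel_rate=0.0, seed=3)
        _, _, _, truth = generate_twin_transcriptomes(cfg)
        idents = np.array([i for _, _, i in truth.ortholog_pairs])
        n_sites = 200 * 600  # conservative: mean length of the 300-900 range
        lo, hi = stats.binom.interval(0.99, n_sites, 0.02)
        assert 100 - 100 * hi / n_sites <= idents.mean() <= 100 - 100 * lo / n_sites

    def test_realized_identity_matches_aligner_within_half_point(self, small_twin):
        set_a, set_b, _, truth = small_twin
        scheme = ScoringScheme()
        for id_a, id_b, identity in truth.ortholog_pairs[:10]:
            hit = local_align(set_a[id_a], set_b[id_b], scheme)
            assert hit.pct_identity == pytest.approx(identity, abs=0.5)

    def test_fragment_fractions_recorded_exactly(self):
        cfg = _cfg(divergence=0.0, indel_rate=0.0,
                   fragment_fractions=(0.25, 0.5, 0.7, 1.0))
        set_a, _, refs, truth = generate_twin_transcriptomes(cfg)
        for id_a, _, _ in truth.ortholog_pairs:
            rec = set_a[id_a]
            frac = truth.coverage_fraction[rec.id]
            ref = refs[f"ref{rec.id[1:]}"]
            assert len(rec) / len(ref) == frac
            assert rec.residues in ref.residues  # exact substring at zero divergence


class TestReads:
    def test_zero_reads_per_transcript(self, small_twin):
        transcripts = small_twin[0]
        reads, _ = generate_reads(transcripts, "ATCAGC",
                                  _cfg(reads_per_transcript=0))
        assert len(reads) == 0

    def test_reads_carry_full_adapter_structure(self, small_twin):
        transcripts = small_twin[0]
        reads, truth = generate_reads(transcripts, "ATCAGC",
                                      _cfg(reads_per_transcript=2))
        assert len(reads) > 0
        for rec in reads:
            assert rec.residues.startswith(ADAPTER_A + "ATCAGC" + ADAPTER_5P)
            assert rec.residues.endswith(ADAPTER_3P + ADAPTER_B)

    def test_inserts_are_exact_substrings_without_errors(self, small_twin):
        transcripts = small_twin[0]
        reads, truth = generate_reads(transcripts, "ATCAGC",
                                      _cfg(reads_per_transcript=2,
                                           homopolymer_error_rate=0.0))
        prefix = len(ADAPTER_A) + 6 + len(ADAPTER_5P)
        suffix = len(ADAPTER_3P) + len(ADAPTER_B)
        for rec in reads:
            origin_id, species, barcode, planted = truth.read_origin[rec.id]
            assert not planted
            insert = rec.residues[prefix:-suffix]
            assert insert in transcripts[origin_id].residues

    def test_planted_run_lengthening_reconstructs_by_alignment(self, small_twin):
        """With error rate 1, the insert differs from its origin by exactly
        one lengthened homopolymer run (verified against the origin)."""
        transcripts = small_twin[0]
        reads, truth = generate_reads(transcripts, "ATCAGC",
                                      _cfg(reads_per_transcript=1,
                                           homopolymer_error_rate=1.0))
        prefix = len(ADAPTER_A) + 6 + len(ADAPTER_5P)
        suffix = len(ADAPTER_3P) + len(ADAPTER_B)
        n_planted = 0
        for rec in reads:
            origin_id, _, _, planted = truth.read_origin[rec.id]
            insert = rec.residues[prefix:-suffix]
            origin = transcripts[origin_id].residues
            if planted:
                n_planted += 1
                assert insert not in origin
                assert _shrinking_one_run_recovers_substring(insert, origin)
            else:
                assert insert in origin
        assert n_planted > 0

    def test_bad_barcode_length_rejected(self, small_twin):
        with pytest.raises(ValueError):
            generate_reads(small_twin[0], "ATC", _cfg())


def _shrinking_one_run_recovers_substring(insert: str, origin: str) -> bool:
    """True iff removing 1-3 bases from one homopolymer run of the insert
    yields an exact substring of the origin transcript."""
    import re

    for m in re.finditer(r"(.)\1\1+", insert):  # runs of >= 3 (2 + extension)
        start, end = m.span()
        for k in (1, 2, 3):
            if end - start - k >= 2:
                candidate = insert[:start] + insert[start : end - k] + insert[end:]
                if candidate in origin:
                    return True
    return False


class TestGOAnnotations:
    def test_no_terms_gives_empty_table(self, small_twin):
        set_a, set_b, _, truth = small_twin
        table, _ = generate_go_annotations(
            set_a, set_b, copy.deepcopy(truth), 0, seed=5)
        assert table == {}

    def test_planted_term_more_frequent_in_specific_set(self):
        cfg = SimulationConfig(n_orthologs=100, n_specific_a=40, n_specific_b=40,
                               seed=21)
        set_a, set_b, _, truth = generate_twin_transcriptomes(cfg)
        table, truth = generate_go_annotations(
            set_a, set_b, truth, 20, [("GO:0000003", "a", 50.0)], seed=8)
        spec = set(truth.specific_a)
        in_spec = sum("GO:0000003" in table.get(t, ()) for t in spec) / len(spec)
        overall = sum("GO:0000003" in table.get(r.id, ()) for r in set_a) / len(set_a)
        assert in_spec > overall
        assert truth.go_truth["GO:0000003"] == "a"
        assert truth.go_truth["GO:0000000"] == "none"

    def test_invalid_multiplier_rejected(self, small_twin):
        set_a, set_b, _, truth = small_twin
        with pytest.raises(ValueError):
            generate_go_annotations(set_a, set_b, copy.deepcopy(truth), 5,
                                    [("GO:0000001", "a", 0.0)], seed=1)

    def test_null_assignment_balanced_between_species(self):
        """Without planted enrichment, per-term frequencies in the two
        specific sets differ only by sampling noise."""
        cfg = SimulationConfig(n_orthologs=50, n_specific_a=60, n_specific_b=60,
                               seed=31)
        set_a, set_b, _, truth = generate_twin_transcriptomes(cfg)
        table, _ = generate_go_annotations(set_a, set_b, truth, 30, seed=13)
        diffs = []
        for i in range(30):
            term = f"GO:{i:07d}"
            fa = sum(term in table.get(t, ()) for t in truth.specific_a) / 60
            fb = sum(term in table.get(t, ()) for t in truth.specific_b) / 60
            diffs.append(fa - fb)
        # mean difference across 30 terms should be near zero
        assert abs(np.mean(diffs)) < 0.05
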
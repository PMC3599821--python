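"""Alignment engine: DP-oracle score agreement, strands, e-values, seeding."""

import math

import numpy as np
import pytest

from twintx.io_formats import SequenceRecord, SequenceSet
from twintx.pairwise_align import (
    ScoringScheme,
    SearchConfig,
    all_vs_all,
    evalue,
    local_align,
    reverse_complement,
)
from twintx.synthetic_data import SimulationConfig, generate_twin_transcriptomes

from oracles import sw_affine_score

SCHEME = ScoringScheme()


def _rec(rec_id, seq):
    return SequenceRecord(id=rec_id, residues=seq)


def _raw_score(hit, scheme=SCHEME):
    """Reconstruct the raw alignment score from the hit's column counts."""
    matches = round(hit.pct_identity * hit.aln_length / 100)
    extends = hit.gap_columns - hit.gap_opens
    return (matches * scheme.match + hit.mismatches * scheme.mismatch
            + hit.gap_opens * scheme.gap_open + extends * scheme.gap_extend)


class TestLocalAlign:
    def test_identical_sequences(self):
        hit = local_align(_rec("q", "ACGTACGT"), _rec("s", "ACGTACGT"), SCHEME)
        assert hit.pct_identity == 100.0
        assert hit.aln_length == 8
        assert (hit.q_start, hit.q_end, hit.s_start, hit.s_end) == (1, 8, 1, 8)

    def test_reverse_strand_hit(self):
        hit = local_align(_rec("q", "AAAA"), _rec("s", "TTTT"), SCHEME)
        assert hit is not None
        assert hit.s_start == 4 and hit.s_end == 1
        assert hit.pct_identity == 100.0 and hit.aln_length == 4

    def test_no_similarity_returns_none(self):
        hit = local_align(_rec("q", "AAAA"), _rec("s", "CCCC"), SCHEME,
                          both_strands=False)
        assert hit is None

    def test_scores_match_full_matrix_dp_oracle(self):
        """500 random pairs <= 60 bp: engine score equals the independent
        Gotoh full-matrix oracle on the better of the two strands."""
        rng = np.random.default_rng(123)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            lq, ls = rng.integers(8, 61, size=2)
            q = "".join(bases[rng.integers(0, 4, size=lq)])
            s = "".join(bases[rng.integers(0, 4, size=ls)])
            expected = max(sw_affine_score(q, s),
                           sw_affine_score(q, reverse_complement(s)))
            hit = local_align(_rec("q", q), _rec("s", s), SCHEME)
            got = 0 if hit is None else _raw_score(hit)
            assert got == expected, (q, s)

    def test_score_symmetry(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            q = "".join(bases[rng.integers(0, 4, size=40)])
            s = "".join(bases[rng.integers(0, 4, size=40)])
            hq = local_align(_rec("q", q), _rec("s", s), SCHEME)
            hs = local_align(_rec("s", s), _rec("q", q), SCHEME)
            assert (hq is None) == (hs is None)
            if hq is not None:
                assert _raw_score(hq) == _raw_score(hs)

    def test_fragment_of_source_is_perfect_hit(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        source = "".join(bases[rng.integers(0, 4, size=400)])
        frag = source[120:280]
        hit = local_align(_rec("f", frag), _rec("s", source), SCHEME)
        assert hit.pct_identity == 100.0
        assert hit.aln_length == len(frag)


class TestEvalue:
    def test_doubling_database_doubles_evalue(self):
        _, e1 = evalue(50, 100, 10_000, SCHEME)
        _, e2 = evalue(50, 100, 20_000, SCHEME)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_zero_bit_score_anchor(self):
        """E * 2^bits == q_len * db_residues, i.e. at bits = 0 the e-value
        equals the search-space size."""
        for raw in (5, 17, 60):
            bits, e = evalue(raw, 137, 9_999, SCHEME)
            assert e * 2 ** bits == pytest.approx(137 * 9_999, rel=1e-9)

    def test_monotone_decreasing_in_score(self):
        evalues = [evalue(s, 100, 10_000, SCHEME)[1] for s in range(5, 100, 7)]
        assert all(a > b for a, b in zip(evalues, evalues[1:]))

    def test_formula_agrees_with_log_space_route(self):
        lam, k = SCHEME.karlin_lambda, SCHEME.karlin_k
        for raw in (3, 30, 120):
            bits, e = evalue(raw, 250, 50_000, SCHEME)
            direct = 250 * 50_000 * k * math.exp(-lam * raw)
            assert e == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_score_rejected(self):
        with pytest.raises(ValueError):
            evalue(0, 100, 1000, SCHEME)


class TestAllVsAll:
    def test_disjoint_sets_give_no_hits(self):
        a = SequenceSet(label="a", records=[_rec("x", "A" * 40)])
        b = SequenceSet(label="b", records=[_rec("y", "ACGT" * 10 + "CGCGT" * 4)])
        cfg = SearchConfig(evalue_cutoff=1e-3)
        # homopolymer A shares no 11-mers with the mixed sequence
        assert all_vs_all(a, b, SCHEME, cfg) == []

    def test_orthologs_find_their_partner(self, small_twin):
        set_a, set_b, _, truth = small_twin
        hits = all_vs_all(set_a, set_b, SCHEME, SearchConfig())
        by_query = {}
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h.subject_id)
        for id_a, id_b, _ in truth.ortholog_pairs:
            assert id_b in by_query.get(id_a, []), f"{id_a} missed {id_b}"

    def test_equals_exhaustive_search_on_small_sets(self):
        """Seeded search output matches seedless all-pairs local alignment
        (same hits, same order) on random 15x15 sets with planted homology."""
        rng = np.random.default_rng(31)
        bases = np.array(list("ACGT"))
        shared = ["".join(bases[rng.integers(0, 4, size=120)]) for _ in range(5)]
        qrecs, srecs = [], []
        for i in range(15):
            if i < 5:
                mut = list(shared[i])
                for pos in rng.integers(0, 120, size=3):
                    mut[pos] = "ACGT"[rng.integers(0, 4)]
                qrecs.append(_rec(f"q{i}", "".join(mut)))
                srecs.append(_rec(f"s{i}", shared[i]))
            else:
                qrecs.append(_rec(f"q{i}", "".join(bases[rng.integers(0, 4, 120)])))
                srecs.append(_rec(f"s{i}", "".join(bases[rng.integers(0, 4, 120)])))
        queries = SequenceSet(label="q", records=qrecs)
        subjects = SequenceSet(label="s", records=srecs)
        cfg = SearchConfig(evalue_cutoff=1e-5)
        seeded = all_vs_all(queries, subjects, SCHEME, cfg)

        db = sum(len(r) for r in subjects)
        exhaustive = []
        for q in queries:
            for s in subjects:
                h = local_align(q, s, SCHEME, db_residues=db)
                if h is not None and h.e_value <= cfg.evalue_cutoff:
                    exhaustive.append(h)
        exhaustive.sort(key=lambda h: (h.query_id, h.e_value, -h.bit_score,
                                       h.subject_id))
        assert seeded == exhaustive

    def test_seeded_recall_on_diverged_orthologs(self):
        """At 5% divergence and k=11 the seeded search recovers >= 99% of
        planted ortholog partners."""
        cfg = SimulationConfig(n_orthologs=100, n_specific_a=0, n_specific_b=0,
                               divergence=0.05, indel_rate=0.0, seed=17)
        set_a, set_b, _, truth = generate_twin_transcriptomes(cfg)
        hits = all_vs_all(set_a, set_b, SCHEME, SearchConfig())
        found = {(h.query_id, h.subject_id) for h in hits}
        recall = sum((a, b) in found for a, b, _ in truth.ortholog_pairs) / len(
            truth.ortholog_pairs)
        assert recall >= 0.99
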
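# Methods

This note documents the models, parameter choices and numerical conventions
behind `twintx`, and what the synthetic-data validation does and does not
demonstrate about real data.

## The analysis problem

Two transcript sets assembled *de novo* from different but closely related
species cannot be compared through a reference genome. The comparison
therefore rests on pairwise sequence alignment: completeness is judged by
how much of a homologous reference each transcript covers (Ortholog Hit
Ratio), orthology by reciprocal best hits, species specificity by the
absence of any qualifying cross-species hit, and functional signal by GO
term enrichment of the specific sets. Every stage of `twintx` is one of
these alignment-derived statistics plus the read-level QC that precedes
assembly.

## Twin-transcriptome simulator

The generator (`twintx.synthetic_data`) emulates the essential structure of
such a dataset:

- **Orthologs.** Each ortholog pair descends from a random ancestor
  (uniform over {A,C,G,T}, length uniform in 300–900 bp, the length regime
  of short-read transcript assemblies). `divergence` is the *pairwise*
  per-site substitution divergence: each descendant copy is mutated at
  `divergence/2`, substitutions uniform over the three alternative bases,
  so `divergence = 0.02` yields a mean alignment identity near 98 %.
  `indel_rate` (single-base insertions/deletions, equal probability) is
  split the same way. Defaults: divergence 0.02, indel rate 0.002 — the
  "sibling species" regime this toolkit targets.
- **Realized identity.** The truth table records, per pair, the percent
  identity of the optimal global alignment of the two copies (match +1,
  mismatch −2, gap open −5, extend −2; gap columns count in the
  denominator), computed once at generation time. This is what an aligner
  can observe, which can differ from the raw edit count when insertions
  create alternative optima.
- **Fragments.** Each ortholog copy may be truncated, from a uniformly
  drawn end, to a fraction drawn from `fragment_fractions`. The recorded
  coverage fraction is the *realized* ratio `len(fragment)/len(ancestor)`
  (truncation lengths are integers), so OHR recovery can be checked for
  exact equality. The full-length ancestors are emitted as the reference
  set. 5′ and 3′ truncation both occur, exercising the N-/C-terminal CDS
  incompleteness classes.
- **Species-specific transcripts.** Unrelated random sequences; at the
  default lengths two random sequences essentially never share the two
  11-mers required for seeding, so the planted specifics define the PDEG
  ground truth.
- **Reads.** Each read is
  `adapterA + 6 bp barcode + 5′ adapter + insert + 3′ adapter + adapterB`
  using the 454 Titanium adapter sequences and the two species barcodes
  (ATCAGC/CACACG) of the target library design; the insert is a random
  transcript substring of 150–350 bp. With probability
  `homopolymer_error_rate`, one homopolymer run (≥ 2 bp) inside the insert
  is lengthened by 1–3 bp, emulating the dominant pyrosequencing error.
  Flowgram noise, quality values and expression-level modelling are
  deliberately out of scope (the target libraries were normalized).
- **GO annotations.** Terms are assigned independently per transcript at a
  per-term base frequency drawn uniform in [0.10, 0.40]; a planted enriched
  term multiplies the assignment *odds* for the designated species'
  specific transcripts. Real GO tables are much sparser; the elevated
  frequencies are chosen so the per-term 2×2 tables are non-degenerate and
  Fisher's exact test is approximately calibrated (see below). Conclusions
  about calibration therefore transfer to real data only where term counts
  are comparably large.

Everything is reproducible from a single seed.

## Alignment engine

Optimal affine-gap local alignment is computed by Biopython's
`PairwiseAligner`; `twintx` adds strand handling, hit construction,
statistics and search orchestration. Conventions:

- Scoring: match +1, mismatch −2, gap open −5, gap extend −2, where a gap
  of length L costs `open + (L−1)·extend`. These resemble standard
  nucleotide-BLAST-style parameters but are not claimed to replicate any
  particular external aligner.
- Percent identity = 100 × matches / alignment columns (gap columns
  included), matching the tabular `pident` convention. One hit per
  query/subject pair: the single best local alignment; no HSP tiling.
- Minus-strand hits are searched via the reverse complement of the subject
  and encoded by `s_start > s_end`.
- E-values use the Karlin–Altschul form `bits = (λS − ln K)/ln 2`,
  `E = mn·2^(−bits)` with fixed constants: λ = ln((3+√21)/2) ≈ 1.3328 is
  the exact ungapped solution of Σ pᵢpⱼ e^{λ sᵢⱼ} = 1 for +1/−2 under
  uniform base composition, and K = 0.621 is the standard tabulated value
  for that scheme. Gapped statistics are not re-estimated: only e-value
  *threshold* behaviour (≤ 1e-5, ≤ 1e-10) matters downstream, and tests
  exercise thresholds, not absolute e-values.
- The all-vs-all search aligns only pairs sharing ≥ 2 distinct 11-mers on
  either strand. Seeding can only remove hits, never invent them; measured
  recall of planted ortholog partners is ≥ 99 % at 5 % divergence.

## Hit-derived statistics

- **Best-hit tiers.** Overlap = 100 × alignment length / query length
  (transcript-centric by design; configurable), identity as above; both
  thresholds applied as ≥. Tier 1 = overlap ≥ 70 % and identity ≥ 50 %,
  tier 2 = overlap only, tier 3 = identity only, tier 4 = neither. Per
  transcript only the best tier present is kept, ties at equal bit score
  broken by subject id for determinism.
- **OHR.** Per hit, (alignment columns − gap columns)/reference length,
  clamped at 1; the maximum over a transcript's hits is reported. Gap
  columns in *either* sequence are subtracted (the "ungapped alignment
  length"). Internal hits carry the exact gap-column count; imported
  12-column hits only carry gap openings, so gap columns are approximated
  by openings (exact for single-base gaps) — a logged, documented
  approximation forced by the tabular format.
- **N50.** The largest length L attained by a sequence such that sequences
  of length ≥ L sum to at least half the total bases; satisfies
  N50 ≥ median on any length multiset.
- **RBH.** A qualifying hit has e-value ≤ 1e-10 and covers ≥ 90 % of its
  query; enforcing the overlap on the query side in each direction means
  both members of an emitted pair satisfy it. Best hit per query by bit
  score, ties by identity then subject id. The reported identity is the
  a→b value; a >1-point disagreement with the b→a value logs a warning.
- **PDEG.** No cross-species hit at e-value ≤ 1e-5 — deliberately the
  looser annotation threshold, not the RBH threshold, so "specific" means
  "not even weakly similar", and PDEG sets are provably disjoint from RBH
  pairs.
- **CDS classes.** All six frames are scanned for maximal stop-free codon
  stretches. A stretch yields: *complete* if it contains ATG and ends at a
  stop inside the transcript; *c_fragment* if it contains ATG but runs off
  the 3′ end; *n_fragment* if it runs off the 5′ end with a terminal stop
  but no ATG; *both_fragment* if it spans the whole frame with neither.
  The longest candidate ≥ 300 bp (100 codons, configurable) wins; equal
  lengths prefer the more complete class, making the call invariant under
  reverse complement. This is a deliberately simple longest-ORF criterion —
  no codon-usage model, no self-training — adequate for the class taxonomy
  and validated only against planted synthetic structure, not against any
  external CDS predictor. "N-terminal" refers to the protein's amino end,
  i.e. the 5′ side of the sense frame.
- **Enrichment.** The 2×2 table compares the test set against *reference
  minus test* so the columns are disjoint, as the test's independence
  assumption requires. Two-sided p-values (sum of hypergeometric
  probabilities ≤ that of the observed table) via scipy; sample odds ratio
  ad/bc with ∞ when bc = 0; a zero margin yields p = 1 with a logged note.
  Benjamini–Hochberg FDR by default (Bonferroni available). GO-graph
  ancestor propagation is not performed; terms are tested as annotated.

## Read cleaning

Adapter A must match at position 0 within 2 mismatches; the following 6-mer
selects the species bin (exact match; otherwise "unassigned"). The 3′-side
adapters are stripped as full matches within the mismatch budget or as
exact truncated prefixes of ≥ 8 bp at the read end. Length (≥ 100 bp) and
N-fraction (≤ 2 %) cutoffs are conventions for this library type, not
universal constants, and are configurable; likewise the rRNA screen
(≥ 90 % identity over ≥ 100 aligned bp against a user-supplied reference).
Every pass conserves counts: each input read lands in exactly one output
bin or removal counter, asserted at run time.

## Validation design and problem sizes

The test suite validates each statistic against an independent route:
full-matrix Gotoh DP for alignment scores (500 random pairs ≤ 60 bp), a
regex/`groupby` scan for homopolymer runs (1000 sequences),
sort-and-accumulate for N50 (1000 length sets), naive min-rank filtering
for best-hit tiers (1000 tables), and hypergeometric enumeration for
Fisher p-values (1000 tables, agreement to 1e-10). End-to-end recovery
runs 200 ortholog pairs with 50 specifics per species — small enough for
minutes-scale runs on one core, large enough that recall/precision bounds
of 0.95 and an identity tolerance of ±0.5 points are meaningful.

Fisher calibration is checked at 20 annotation draws × 100 terms: the
fraction of null raw p-values ≤ 0.05 must lie in [0.03, 0.07] — the lower
bound acknowledges that the exact test is conservative on discrete tables —
and a term planted at odds multiplier 50 must rank first with adjusted
p ≤ 0.05 in ≥ 19/20 draws.

Passing these tests shows the statistics are computed correctly and that
the pipeline recovers planted structure under an idealized error model; it
does not certify performance on real pyrosequencing data, where coverage
heterogeneity, chimeras, paralogy and assembly artifacts (none of which
the simulator models) degrade ortholog calling in ways no synthetic check
can capture.

## Known limitations

- Nucleotide-only alignment: protein-space (translated) annotation against
  external databases is out of scope, though imported protein hit tables
  are consumed (OHR units then follow the table, amino acids).
- One best alignment per pair; tiling of multiple HSPs is not performed.
- The CDS classifier is a longest-ORF proxy, standard genetic code only.
- GO enrichment treats terms independently; no DAG decorrelation or slim
  mapping.
- The simulator's mutation model is symmetric and site-independent; no
  rate heterogeneity, no paralog families, no expression model.
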
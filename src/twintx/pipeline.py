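"""End-to-end orchestration: simulate -> clean -> QC -> align -> compare.

Every stage writes a plain TSV or FASTA artifact into the output directory
so any step can be rerun or inspected standalone; the consolidated
:class:`ComparisonReport` only aggregates numbers that are recomputable
from those artifacts.  Identical config + seed reproduces identical
artifacts byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import (
    cross_species,
    go_enrichment,
    hit_analysis,
    homopolymer_qc,
    read_cleaning,
    synthetic_data,
)
from .io_formats import SequenceSet, write_fasta, write_table, write_tabular_hits
from .orf_completeness import class_counts, classify_cds
from .pairwise_align import ScoringScheme, SearchConfig, all_vs_all
from .synthetic_data import SimulationConfig, write_truth_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ComparisonReport", "run_pipeline"]

_ALL_STAGES = ("simulate", "clean", "hpoly", "align", "ohr", "cds",
               "rbh", "pdeg", "enrich", "stats")


@dataclass
class PipelineConfig:
    """One config object spanning every stage.

    ``seed`` drives every stochastic stage; stages absent from ``stages``
    are skipped (downstream stages needing their outputs are then skipped
    too, with a log line).
    """

    outdir: Path = Path("twintx_out")
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cleaning_kwargs: dict = field(default_factory=dict)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    search: SearchConfig = field(default_factory=SearchConfig)
    rbh_evalue_max: float = cross_species.RBH_EVALUE_MAX
    rbh_min_overlap_pct: float = cross_species.RBH_MIN_OVERLAP_PCT
    pdeg_evalue_max: float = cross_species.PDEG_EVALUE_MAX
    divergent_cutoff: float = cross_species.DIVERGENT_IDENTITY_CUTOFF
    n_go_terms: int = 50
    enriched_terms: list = field(default_factory=list)
    min_orf_bp: int = 300

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")


@dataclass
class ComparisonReport:
    """Consolidated cross-species comparison numbers."""

    assembly_stats: dict = field(default_factory=dict)
    homopolymer_means: dict = field(default_factory=dict)
    cleaning: dict = field(default_factory=dict)
    ohr_summary: dict = field(default_factory=dict)
    cds_counts: dict = field(default_factory=dict)
    rbh: dict = field(default_factory=dict)
    pdeg_counts: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    def rows(self) -> list[dict[str, object]]:
        out = []
        for section, payload in asdict(self).items():
            for key, value in _flatten(payload, section):
                out.append({"metric": key, "value": value})
        return out


def _flatten(d: dict, prefix: str):
    for key, value in d.items():
        name = f"{prefix}.{key}"
        if isinstance(value, dict):
            yield from _flatten(value, name)
        else:
            yield name, value


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Execute the enabled stages in dependency order; see module docstring."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report = ComparisonReport()
    enabled = set(config.stages)
    if not enabled:
        logger.info("all stages disabled; writing empty report")
        _write_report(report, outdir)
        return report

    sim = config.simulation
    if sim.seed != config.seed:
        sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})

    set_a = set_b = refs = truth = None
    if "simulate" in enabled:
        set_a, set_b, refs, truth = synthetic_data.generate_twin_transcriptomes(sim)
        write_fasta(set_a, outdir / "species_a.fasta")
        write_fasta(set_b, outdir / "species_b.fasta")
        write_fasta(refs, outdir / "references.fasta")
        logger.info("simulate: %d + %d transcripts, %d references",
                    len(set_a), len(set_b), len(refs))

    if "clean" in enabled and set_a is not None and sim.reads_per_transcript > 0:
        rng = np.random.default_rng(sim.seed + 1)
        reads_a, truth = synthetic_data.generate_reads(
            set_a, "CACACG", sim, truth, rng)
        reads_b, truth = synthetic_data.generate_reads(
            set_b, "ATCAGC", sim, truth, rng)
        all_reads = SequenceSet(
            label="reads", records=list(reads_a.records) + list(reads_b.records))
        write_fasta(all_reads, outdir / "reads_raw.fasta")
        clean_cfg = read_cleaning.CleaningConfig(**config.cleaning_kwargs)
        bins, demux_report = read_cleaning.demultiplex_and_trim(all_reads, clean_cfg)
        cleaned = {}
        for species, seqs in bins.items():
            if species == "unassigned" or len(seqs) == 0:
                continue
            filtered, filt_report = read_cleaning.filter_reads(seqs, clean_cfg)
            screened, rrna_report = read_cleaning.screen_rrna(filtered, clean_cfg)
            if len(screened):
                write_fasta(screened, outdir / f"reads_clean_{species}.fasta")
            cleaned[species] = {
                "input": len(seqs),
                "removed_short": filt_report.removed_short,
                "removed_high_n": filt_report.removed_high_n,
                "removed_rrna": rrna_report.removed_rrna,
                "output": len(screened),
            }
        report.cleaning = {
            "input_count": demux_report.input_count,
            "unassigned": demux_report.unassigned_barcode,
            "adapter_only": demux_report.adapter_only,
            **{f"species.{sp}": counts for sp, counts in cleaned.items()},
        }
        logger.info("clean: %d reads in, %d unassigned",
                    demux_report.input_count, demux_report.unassigned_barcode)

    if "stats" in enabled and set_a is not None:
        for label, seqs in (("a", set_a), ("b", set_b)):
            report.assembly_stats[label] = asdict(hit_analysis.assembly_stats(seqs))
        write_table(
            [{"species": sp, **st} for sp, st in report.assembly_stats.items()],
            outdir / "assembly_stats.tsv")
        logger.info("stats: written for both species")

    if "hpoly" in enabled and set_a is not None:
        for label, seqs in (("a", set_a), ("b", set_b)):
            prof = homopolymer_qc.profile(seqs)
            report.homopolymer_means[label] = dict(prof.mean_longest)
            report.homopolymer_means[f"{label}_global_max"] = prof.global_max
            write_table(prof.to_rows(), outdir / f"homopolymer_{label}.tsv",
                        fieldnames=["nucleotide", "run_length", "count"])
        logger.info("hpoly: profiles written")

    hits_ab = hits_ba = None
    if "align" in enabled and set_a is not None:
        hits_ab = all_vs_all(set_a, set_b, config.scoring, config.search)
        hits_ba = all_vs_all(set_b, set_a, config.scoring, config.search)
        write_tabular_hits(hits_ab, outdir / "hits_ab.tsv")
        write_tabular_hits(hits_ba, outdir / "hits_ba.tsv")
        logger.info("align: %d a->b hits, %d b->a hits", len(hits_ab), len(hits_ba))

    if "ohr" in enabled and set_a is not None and refs is not None:
        for label, seqs in (("a", set_a), ("b", set_b)):
            ref_hits = all_vs_all(seqs, refs, config.scoring, config.search)
            records = hit_analysis.ohr_table(ref_hits)
            write_table([asdict(r) for r in records], outdir / f"ohr_{label}.tsv",
                        fieldnames=["transcript_id", "best_subject_id", "ohr",
                                    "n_hits_considered"])
            report.ohr_summary[label] = hit_analysis.ohr_summary(records)
        logger.info("ohr: summaries %s", report.ohr_summary)

    if "cds" in enabled and set_a is not None:
        for label, seqs in (("a", set_a), ("b", set_b)):
            calls = [classify_cds(rec, config.min_orf_bp) for rec in seqs]
            write_table([asdict(c) for c in calls], outdir / f"cds_{label}.tsv")
            report.cds_counts[label] = class_counts(calls)
        logger.info("cds: class counts %s", report.cds_counts)

    pairs = None
    if "rbh" in enabled and hits_ab is not None:
        pairs = cross_species.reciprocal_best_hits(
            hits_ab, hits_ba, config.rbh_evalue_max, config.rbh_min_overlap_pct)
        write_table([asdict(p) for p in pairs], outdir / "rbh_pairs.tsv",
                    fieldnames=["id_a", "id_b", "pct_identity", "overlap_a",
                                "overlap_b", "evalue_ab", "evalue_ba"])
        if pairs:
            div = cross_species.divergence_report(pairs, config.divergent_cutoff)
            report.rbh = {
                "n_pairs": div.n_pairs,
                "mean_identity": div.mean_identity,
                "min_identity": div.min_identity,
                "max_identity": div.max_identity,
                "median_identity": div.median_identity,
                "n_divergent": len(div.divergent_pairs),
            }
        else:
            report.rbh = {"n_pairs": 0}
        logger.info("rbh: %d pairs", len(pairs))

    pdeg = {}
    if "pdeg" in enabled and hits_ab is not None:
        pdeg["a"] = cross_species.species_specific(
            set_a, hits_ab, config.pdeg_evalue_max)
        pdeg["b"] = cross_species.species_specific(
            set_b, hits_ba, config.pdeg_evalue_max)
        for label in ("a", "b"):
            (outdir / f"pdeg_{label}.txt").write_text(
                "".join(f"{tid}\n" for tid in pdeg[label]))
        report.pdeg_counts = {k: len(v) for k, v in pdeg.items()}
        logger.info("pdeg: %s", report.pdeg_counts)

    if "enrich" in enabled and pdeg and truth is not None:
        go_table, truth = synthetic_data.generate_go_annotations(
            set_a, set_b, truth, config.n_go_terms,
            config.enriched_terms, seed=config.seed + 2)
        go_enrichment.write_go_table(go_table, outdir / "go_annotations.tsv")
        for label, seqs in (("a", set_a), ("b", set_b)):
            if not pdeg.get(label):
                continue
            results = go_enrichment.enrich(pdeg[label], seqs.ids, go_table)
            write_table([asdict(r) for r in results],
                        outdir / f"enrichment_{label}.tsv",
                        fieldnames=["term", "a_count", "b_count", "a_total",
                                    "b_total", "odds_ratio", "p_value",
                                    "p_adjusted", "direction"])
            report.enrichment[label] = {
                "n_terms_tested": len(results),
                "n_significant": sum(r.p_adjusted <= 0.05 for r in results),
            }
        logger.info("enrich: %s", report.enrichment)

    if truth is not None:
        write_truth_table(truth, outdir / "truth.tsv")
    _write_report(report, outdir)
    return report


def _write_report(report: ComparisonReport, outdir: Path) -> None:
    rows = report.rows()
    write_table(rows, outdir / "report.tsv", fieldnames=["metric", "value"])
    lines = [f"{r['metric']}\t{r['value']}" for r in rows]
    (outdir / "report.txt").write_text(
        "cross-species comparison report\n" + "\n".join(lines) + "\n")
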
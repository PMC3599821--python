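"""Fisher's exact GO-term enrichment of a transcript subset.

Tests, per GO term, whether a subset (e.g. the species-specific PDEG set)
is annotated with the term at a different rate than the rest of its
species' transcripts.  The 2x2 table compares the test set against
*reference minus test* so the two columns are disjoint, as Fisher's exact
test assumes.  Two-sided p-values come from summing hypergeometric
probabilities of all tables (margins fixed) no more probable than the
observed one; multiple testing is controlled by Benjamini–Hochberg FDR
(Bonferroni available).

Terms are tested exactly as annotated: no GO-graph ancestor propagation.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "fisher_exact", "enrich",
           "read_go_table", "write_go_table"]

_GO_ID = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment call for one GO term.

    ``a_count``/``a_total`` refer to the test set, ``b_count``/``b_total``
    to the reference-minus-test complement; ``direction`` is "over" when
    the term is more frequent in the test set than in the complement.
    """

    term: str
    a_count: int
    b_count: int
    a_total: int
    b_total: int
    odds_ratio: float
    p_value: float
    p_adjusted: float
    direction: str


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns the sample odds ratio ``a*d / (b*c)`` (infinity when ``b*c``
    is zero and ``a*d`` positive) and the two-sided p-value.  A table with
    a zero margin carries no information; p is 1.0 with a logged note.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        logger.info("fisher_exact: degenerate margin in table (%d,%d,%d,%d); p=1",
                    a, b, c, d)
        odds = _sample_odds_ratio(a, b, c, d)
        return odds, 1.0
    result = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return _sample_odds_ratio(a, b, c, d), float(result.pvalue)


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def enrich(
    test_ids: Iterable[str],
    reference_ids: Iterable[str],
    go: Mapping[str, set[str]],
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Per-term enrichment of ``test_ids`` within ``reference_ids``.

    The test set must be a subset of the reference set; each term annotated
    anywhere in the reference is tested with the table (in-test with term,
    in-test without, in-complement with, in-complement without).  Results
    are sorted by adjusted p-value (then raw p, then term id).
    ``method`` is any statsmodels multipletests method name.
    """
    test = list(dict.fromkeys(test_ids))
    reference = list(dict.fromkeys(reference_ids))
    if not test:
        raise ValueError("enrichment requires a non-empty test set")
    test_set = set(test)
    ref_set = set(reference)
    if not test_set <= ref_set:
        raise ValueError("test ids must be a subset of the reference ids")
    complement = [tid for tid in reference if tid not in test_set]

    terms = sorted({t for tid in reference for t in go.get(tid, ())})
    if not terms:
        return []
    a_total, b_total = len(test), len(complement)

    rows = []
    for term in terms:
        a = sum(1 for tid in test if term in go.get(tid, ()))
        c = sum(1 for tid in complement if term in go.get(tid, ()))
        b, d = a_total - a, b_total - c
        odds, p = fisher_exact(a, c, b, d)
        freq_test = a / a_total if a_total else 0.0
        freq_ref = c / b_total if b_total else 0.0
        rows.append((term, a, c, odds, p,
                     "over" if freq_test > freq_ref else "under"))

    p_values = [r[4] for r in rows]
    _, p_adj, _, _ = multipletests(p_values, alpha=alpha, method=method)
    results = [
        EnrichmentResult(term=term, a_count=a, b_count=c,
                         a_total=a_total, b_total=b_total,
                         odds_ratio=odds, p_value=p,
                         p_adjusted=float(adj), direction=direction)
        for (term, a, c, odds, p, direction), adj in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.term))
    return results


def read_go_table(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV of (transcript_id, GO id), one pair per line."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            tid, term = parts
            if not _GO_ID.match(term):
                raise ValueError(f"{path}: line {lineno}: malformed GO id {term!r}")
            table.setdefault(tid, set()).add(term)
    return table


def write_go_table(table: Mapping[str, Sequence[str] | set[str]],
                   path: str | Path) -> Path:
    path = Path(path)
    with open(path, "wt") as fh:
        for tid in sorted(table):
            for term in sorted(table[tid]):
                fh.write(f"{tid}\t{term}\n")
    return path
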
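"""Independent brute-force oracles used across the test suite.

Each oracle recomputes a quantity by the most transparent method available
(full-matrix DP, regex scan, sort-and-accumulate, exhaustive enumeration),
deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math
import re
from itertools import groupby


def sw_affine_score(q: str, s: str, match: int = 1, mismatch: int = -2,
                    gap_open: int = -5, gap_extend: int = -2) -> int:
    """Optimal local alignment score by full-matrix Gotoh DP.

    Convention: a gap of length L scores gap_open + (L-1)*gap_extend.
    """
    n, m = len(q), len(s)
    neg = -(10 ** 9)
    h_prev = [0] * (m + 1)
    e_row = [neg] * (m + 1)
    f_prev = [neg] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        h_cur = [0] * (m + 1)
        f_cur = [neg] * (m + 1)
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_row[j] = max(h_cur[j - 1] + gap_open, e_row[j - 1] + gap_extend)
            f_cur[j] = max(h_prev[j] + gap_open, f_prev[j] + gap_extend)
            diag = h_prev[j - 1] + (match if qi == s[j - 1] else mismatch)
            h_cur[j] = max(0, diag, e_row[j], f_cur[j])
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev, f_prev = h_cur, f_cur
        e_row = [neg] * (m + 1)
    return best


def longest_runs_regex(seq: str) -> dict[str, int]:
    """Longest run per nucleotide via regex findall (N breaks runs)."""
    out = {}
    for base in "ACGT":
        runs = re.findall(f"{base}+", seq)
        out[base] = max((len(r) for r in runs), default=0)
    return out


def longest_runs_groupby(seq: str) -> dict[str, int]:
    """Second independent route: itertools.groupby run-length encoding."""
    out = dict.fromkeys("ACGT", 0)
    for base, group in groupby(seq):
        if base in out:
            out[base] = max(out[base], sum(1 for _ in group))
    return out


def n50_brute(lengths: list[int]) -> int:
    """N50 by sort-descending-and-accumulate."""
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc * 2 >= total:
            return length
    raise AssertionError("unreachable for non-empty input")


def best_tier_filter_brute(hits, categorize) -> dict[str, list]:
    """Min-rank-then-filter, spelled out naively."""
    queries = {h.query_id for h in hits}
    out = {}
    for qid in queries:
        mine = [h for h in hits if h.query_id == qid]
        ranks = [categorize(h).rank for h in mine]
        best = min(ranks)
        out[qid] = sorted(
            (h for h, r in zip(mine, ranks) if r == best),
            key=lambda h: (-h.bit_score, h.subject_id),
        )
    return out


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_hyper(x: int) -> float:
        # probability of table [[x, r1-x], [c1-x, r2-c1+x]] given margins
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = log_hyper(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p_x = log_hyper(x)
        if p_x <= p_obs + 1e-9:  # tolerance for log-space ties
            total += math.exp(p_x)
    return min(1.0, total)
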
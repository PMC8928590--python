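"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (O(n^2) scans, exhaustive
enumeration) and shares no code with the package's vectorized paths.
"""

from __future__ import annotations

import math
from collections import defaultdict


def brute_merge(intervals, gap=0):
    """Pairwise-absorption merge of (chrom, start, end) triples."""
    items = [list(t) for t in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            if items[i] is None:
                continue
            for j in range(len(items)):
                if i == j or items[j] is None:
                    continue
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci != cj:
                    continue
                if sj <= ei + gap and si <= ej + gap:
                    items[i] = [ci, min(si, sj), max(ei, ej)]
                    items[j] = None
                    changed = True
        items = [x for x in items if x is not None] + [None] * 0
    return sorted((c, s, e) for c, s, e in items)


def brute_covered_bp(intervals):
    """Union bp via per-chromosome position sets (coords must be small)."""
    cover = defaultdict(set)
    for c, s, e in intervals:
        cover[c].update(range(s, e))
    return sum(len(v) for v in cover.values())


def brute_subtract(a_intervals, b_intervals):
    """(chrom, start, end) triples of union(a) minus union(b), per-bp."""
    keep = defaultdict(set)
    for c, s, e in a_intervals:
        keep[c].update(range(s, e))
    for c, s, e in b_intervals:
        if c in keep:
            keep[c].difference_update(range(s, e))
    out = []
    for c in sorted(keep):
        pos = sorted(keep[c])
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] == pos[j] + 1:
                j += 1
            out.append((c, pos[i], pos[j] + 1))
            i = j + 1
    return out


def brute_flanks(intervals, size, chrom_lengths):
    """Per-region construct-then-subtract flank oracle."""
    raw = []
    for c, s, e in intervals:
        L = chrom_lengths[c]
        if s > 0:
            raw.append((c, max(0, s - size), s))
        if e < L:
            raw.append((c, e, min(L, e + size)))
    return brute_subtract(raw, intervals)


def brute_repeat_content(target, features):
    """Per-feature intersection scan against the merged target.

    target: (chrom, start, end) triples; features: (chrom, start, end, cls).
    Returns {cls: (overlap_bp, count)} plus the merged target bp.
    """
    merged = brute_merge(target, 0)
    out = defaultdict(lambda: [0, 0])
    for fc, fs, fe, cls in features:
        bp = 0
        hit = False
        for tc, ts, te in merged:
            if tc != fc:
                continue
            ov = min(fe, te) - max(fs, ts)
            if ov > 0:
                bp += ov
                hit = True
        out[cls][0] += bp
        out[cls][1] += 1 if hit else 0
    footprint = sum(e - s for _, s, e in merged)
    return {k: tuple(v) for k, v in out.items()}, footprint


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(k):
        # P(X = k) for X hypergeometric(n, row1, col1)
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(n, col1)
        )

    p_obs = table_prob(a)
    total = 0.0
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = table_prob(k)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)
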
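"""Cross-sample CNV event clustering and multi-group sharing summaries.

Filtered DEL/DUP calls from every sample are clustered into *events*:
single-linkage over same-type calls that satisfy the overlap rule (default
>= 1 bp overlap; a 50% reciprocal-overlap mode is available).  A cluster
with exactly one member call is a *singleton* — the variant was seen once
in one sample — and is removed before the sharing analysis.  Surviving
events are assigned to one of the 7 nonempty Venn categories over the three
groups (e.g. Sample1-sperms, Sample2-sperms, Sample1-trio), and
event-count and length percentages are summarized per category.

Cluster length is the union footprint of the member calls; the
sum-of-member-lengths convention is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .regions import Region, covered_bp
from .variants import CNV_TYPES, SVCall

__all__ = [
    "EventCluster",
    "OverlapRule",
    "cluster_events",
    "remove_singletons",
    "venn_summary",
    "venn_category",
    "clusters_frame",
]


@dataclass(frozen=True)
class OverlapRule:
    """Overlap criterion joining two same-type calls into one event."""

    min_overlap_bp: int = 1
    reciprocal: float = 0.0  # e.g. 0.5 for 50% reciprocal overlap

    def matches(self, a: SVCall, b: SVCall) -> bool:
        if a.chrom != b.chrom or a.svtype != b.svtype:
            return False
        ov = min(a.end, b.end) - max(a.start, b.start)
        if ov < max(1, self.min_overlap_bp):
            return False
        if self.reciprocal > 0.0:
            if ov < self.reciprocal * a.length or ov < self.reciprocal * b.length:
                return False
        return True


@dataclass(frozen=True)
class EventCluster:
    """One CNV event: same-type calls linked by overlap across samples."""

    svtype: str
    members: tuple[SVCall, ...]
    region: Region                 # span of the member union
    groups_present: frozenset[str]
    length_union: int
    length_sum: int

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    @property
    def venn_category(self) -> str:
        return "&".join(sorted(self.groups_present))


def venn_category(groups: Iterable[str]) -> str:
    return "&".join(sorted(set(groups)))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_events(
    calls: Sequence[SVCall], rule: OverlapRule = OverlapRule()
) -> list[EventCluster]:
    """Single-linkage clustering of DEL/DUP calls under the overlap rule.

    Input order does not matter: calls are sorted internally, and the
    output is ordered by (svtype, chrom, start).
    """
    cnvs = [c for c in calls if c.svtype in CNV_TYPES]
    cnvs.sort(key=lambda c: (c.svtype, c.chrom, c.start, c.end, c.sample_id))
    uf = _UnionFind(len(cnvs))
    # sweep within (svtype, chrom) blocks; only overlapping pairs can match
    block_start = 0
    for i, c in enumerate(cnvs):
        if i > 0 and (c.svtype != cnvs[i - 1].svtype or c.chrom != cnvs[i - 1].chrom):
            block_start = i
        j = i - 1
        while j >= block_start:
            other = cnvs[j]
            # sorted by start: once starts are far left, overlap may still
            # occur via long regions, so scan the whole block (blocks are
            # small in practice); cheap early exit on max possible end
            if rule.matches(c, other):
                uf.union(i, j)
            j -= 1

    groups: dict[int, list[SVCall]] = {}
    for i in range(len(cnvs)):
        groups.setdefault(uf.find(i), []).append(cnvs[i])

    clusters = []
    for members in groups.values():
        members.sort(key=lambda c: (c.start, c.end, c.sample_id))
        chrom = members[0].chrom
        start = min(c.start for c in members)
        end = max(c.end for c in members)
        clusters.append(
            EventCluster(
                svtype=members[0].svtype,
                members=tuple(members),
                region=Region(chrom, start, end),
                groups_present=frozenset(c.group for c in members),
                length_union=covered_bp(members),
                length_sum=sum(c.length for c in members),
            )
        )
    clusters.sort(key=lambda cl: (cl.svtype, cl.region.chrom, cl.region.start))
    return clusters


def remove_singletons(clusters: Iterable[EventCluster]) -> list[EventCluster]:
    """Drop events backed by exactly one call in one sample.

    A variant seen in >= 2 sperm cells of one bull occurred more than once
    and is therefore kept, even though only one group is involved.
    """
    return [cl for cl in clusters if not cl.is_singleton]


def venn_summary(clusters: Sequence[EventCluster]) -> pd.DataFrame:
    """Per-Venn-category event counts/percentages and length percentages.

    Percentages are of the total event count / total length and rounded to
    2 decimals.  Both the union and sum-of-members length conventions are
    reported.
    """
    total = len(clusters)
    total_union = sum(cl.length_union for cl in clusters)
    total_sum = sum(cl.length_sum for cl in clusters)
    by_cat: dict[str, list[EventCluster]] = {}
    for cl in clusters:
        by_cat.setdefault(cl.venn_category, []).append(cl)
    rows = []
    for cat in sorted(by_cat):
        cls = by_cat[cat]
        n = len(cls)
        lu = sum(c.length_union for c in cls)
        ls = sum(c.length_sum for c in cls)
        rows.append(
            {
                "category": cat,
                "n_groups": cat.count("&") + 1,
                "n_events": n,
                "pct_events": round(100.0 * n / total, 2) if total else 0.0,
                "length_union_bp": lu,
                "pct_length_union": round(100.0 * lu / total_union, 2)
                if total_union else 0.0,
                "length_sum_bp": ls,
                "pct_length_sum": round(100.0 * ls / total_sum, 2)
                if total_sum else 0.0,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "category", "n_groups", "n_events", "pct_events",
            "length_union_bp", "pct_length_union",
            "length_sum_bp", "pct_length_sum",
        ],
    )
    df.attrs["total_events"] = total
    df.attrs["total_length_union_bp"] = total_union
    df.attrs["total_length_sum_bp"] = total_sum
    return df


def clusters_frame(clusters: Sequence[EventCluster]) -> pd.DataFrame:
    """Flat cluster table for TSV export."""
    rows = []
    for i, cl in enumerate(clusters):
        rows.append(
            {
                "event_id": f"cluster_{i:05d}",
                "svtype": cl.svtype,
                "chrom": cl.region.chrom,
                "start": cl.region.start,
                "end": cl.region.end,
                "n_members": len(cl.members),
                "is_singleton": cl.is_singleton,
                "venn_category": cl.venn_category,
                "length_union_bp": cl.length_union,
                "length_sum_bp": cl.length_sum,
                "samples": ",".join(sorted({m.sample_id for m in cl.members})),
            }
        )
    return pd.DataFrame(rows)
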
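"""Interval algebra on genomic regions.

All coordinates are 0-based half-open ``[start, end)``.  Operations accept
any sequence of objects exposing ``chrom``/``start``/``end`` attributes
(:class:`Region`, SV calls, repeat features ...) and return plain
:class:`Region` lists sorted by (chromosome, start).

The merge used for "neighboring" regions joins intervals that overlap or
whose separation is at most ``gap`` bp; with ``gap=0`` book-ended intervals
([10,20) and [20,30)) are joined, matching the usual union footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeDef

__all__ = [
    "Region",
    "merge_regions",
    "covered_bp",
    "subtract_regions",
    "intersect_regions",
    "flank_regions",
    "per_chromosome_summary",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class Region:
    """A genomic interval with an optional label payload."""

    chrom: str
    start: int
    end: int
    payload: Mapping[str, object] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _group_by_chrom(regions: Iterable) -> dict[str, np.ndarray]:
    """Group intervals by chromosome into sorted (n, 2) int arrays."""
    buckets: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        buckets.setdefault(r.chrom, []).append((r.start, r.end))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in buckets.items():
        arr = np.asarray(ivs, dtype=np.int64)
        arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
        out[chrom] = arr
    return out


def _chrom_sort_key(genome: GenomeDef | None):
    if genome is None:
        return lambda c: (c,)
    order = {name: i for i, name in enumerate(genome.names)}
    return lambda c: (order.get(c, len(order)), c)


def _merge_array(arr: np.ndarray, gap: int) -> np.ndarray:
    """Merge a sorted (n, 2) interval array; separation <= gap joins."""
    if len(arr) == 0:
        return arr
    s, e = arr[:, 0], np.maximum.accumulate(arr[:, 1])
    new = np.empty(len(arr), dtype=bool)
    new[0] = True
    new[1:] = s[1:] > e[:-1] + gap
    starts = s[new]
    last = np.r_[np.nonzero(new)[0][1:] - 1, len(arr) - 1]
    ends = e[last]
    return np.column_stack([starts, ends])


def merge_regions(
    regions: Sequence, gap: int = 0, genome: GenomeDef | None = None
) -> list[Region]:
    """Merge overlapping / near-adjacent intervals into a disjoint set.

    Two intervals are joined when they overlap, are book-ended, or are
    separated by at most ``gap`` bp.  The output is sorted and pairwise
    disjoint; for ``gap=0`` the total covered bp is preserved.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    key = _chrom_sort_key(genome)
    out: list[Region] = []
    grouped = _group_by_chrom(regions)
    for chrom in sorted(grouped, key=key):
        for s, e in _merge_array(grouped[chrom], gap):
            out.append(Region(chrom, int(s), int(e)))
    return out


def covered_bp(regions: Sequence) -> int:
    """Total bp of the union footprint of ``regions``."""
    total = 0
    for arr in _group_by_chrom(regions).values():
        m = _merge_array(arr, 0)
        total += int((m[:, 1] - m[:, 0]).sum())
    return total


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """a minus b; both sorted disjoint (n, 2) arrays on one chromosome."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def subtract_regions(
    regions: Sequence, mask: Sequence, genome: GenomeDef | None = None
) -> list[Region]:
    """Union footprint of ``regions`` minus union footprint of ``mask``."""
    key = _chrom_sort_key(genome)
    a_by = {c: _merge_array(arr, 0) for c, arr in _group_by_chrom(regions).items()}
    b_by = {c: _merge_array(arr, 0) for c, arr in _group_by_chrom(mask).items()}
    out: list[Region] = []
    for chrom in sorted(a_by, key=key):
        b = b_by.get(chrom, np.empty((0, 2), dtype=np.int64))
        for s, e in _subtract_arrays(a_by[chrom], b):
            out.append(Region(chrom, int(s), int(e)))
    return out


def intersect_regions(
    regions: Sequence, other: Sequence, genome: GenomeDef | None = None
) -> list[Region]:
    """Union footprint of ``regions`` intersected with that of ``other``."""
    key = _chrom_sort_key(genome)
    a_by = {c: _merge_array(arr, 0) for c, arr in _group_by_chrom(regions).items()}
    b_by = {c: _merge_array(arr, 0) for c, arr in _group_by_chrom(other).items()}
    out: list[Region] = []
    for chrom in sorted(a_by, key=key):
        if chrom not in b_by:
            continue
        a, b = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(a) and j < len(b):
            s = max(a[i, 0], b[j, 0])
            e = min(a[i, 1], b[j, 1])
            if s < e:
                out.append(Region(chrom, int(s), int(e)))
            if a[i, 1] < b[j, 1]:
                i += 1
            else:
                j += 1
    return out


def flank_regions(
    regions: Sequence,
    size: int,
    genome: GenomeDef,
    subtract_inputs: bool = True,
) -> list[Region]:
    """Flanking windows of ``size`` bp on each side of every region.

    Flanks are clipped at chromosome bounds, so a region starting at the
    chromosome end has no left flank.  Under the default policy any overlap
    with ANY input region is subtracted, so flanks never re-cover input
    footprint (flanks of nearby regions are truncated accordingly).
    """
    if size <= 0:
        raise ValueError("flank size must be > 0")
    raw: list[Region] = []
    for r in regions:
        chrom_len = genome.length_of(r.chrom)
        ls, le = max(0, r.start - size), r.start
        if ls < le:
            raw.append(Region(r.chrom, ls, le, {"side": "left"}))
        rs, re = r.end, min(chrom_len, r.end + size)
        if rs < re:
            raw.append(Region(r.chrom, rs, re, {"side": "right"}))
    if not subtract_inputs:
        return sorted(raw, key=lambda r: (_chrom_sort_key(genome)(r.chrom), r.start))
    return subtract_regions(raw, regions, genome)


def per_chromosome_summary(regions: Sequence, genome: GenomeDef) -> pd.DataFrame:
    """Per-chromosome region count, merged footprint bp, and % covered."""
    counts: dict[str, int] = {name: 0 for name in genome.names}
    for r in regions:
        if r.chrom not in counts:
            raise KeyError(f"region on chromosome {r.chrom!r} absent from genome")
        counts[r.chrom] += 1
    merged = _group_by_chrom(regions)
    rows = []
    for name, length in genome:
        arr = merged.get(name)
        bp = 0 if arr is None else int(np.diff(_merge_array(arr, 0), axis=1).sum())
        rows.append(
            {
                "chrom": name,
                "n_regions": counts[name],
                "covered_bp": bp,
                "pct_covered": round(100.0 * bp / length, 2),
            }
        )
    return pd.DataFrame(rows)


# -- BED I/O ------------------------------------------------------------------


def write_bed(regions: Sequence, path: str | Path, name_key: str | None = None) -> None:
    """Write BED3 (or BED4 when ``name_key`` selects a payload field)."""
    with open(path, "w") as fh:
        for r in regions:
            if name_key is not None:
                name = (getattr(r, "payload", None) or {}).get(name_key, ".")
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bed(path: str | Path) -> list[Region]:
    out: list[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            payload = {"name": parts[3]} if len(parts) > 3 else None
            out.append(Region(parts[0], int(parts[1]), int(parts[2]), payload))
    return out
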
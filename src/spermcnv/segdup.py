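"""Pairwise segmental-duplication fragment tables and their summaries.

A segmental duplication (SegDup, low copy repeat) detector reports *pairs*
of highly similar genomic fragments.  This module consumes such pairwise
tables, deduplicates fragments into a nonredundant region set, and computes
the identity / orientation / chromosomal-distribution summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .regions import Region

__all__ = [
    "SegDupPair",
    "PairSummary",
    "nonredundant_fragments",
    "summarize_segdup_pairs",
    "read_pair_table",
    "write_pair_table",
]


@dataclass(frozen=True)
class SegDupPair:
    """Two genomic fragments with sequence identity and relative orientation."""

    fragment_a: Region
    fragment_b: Region
    identity: float
    same_orientation: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside (0, 1]")

    @property
    def interchromosomal(self) -> bool:
        return self.fragment_a.chrom != self.fragment_b.chrom


@dataclass(frozen=True)
class PairSummary:
    """Summary of a pairwise SegDup fragment table.

    Percentages are of ``n_pairs`` and rounded to 2 decimals; identity
    thresholds use a strict ``>`` comparison.
    """

    n_pairs: int
    pct_identity_gt: dict[float, float]
    pct_reversed: float
    pct_interchromosomal: float
    n_unique_fragments: int


def nonredundant_fragments(pairs: Iterable[SegDupPair]) -> list[Region]:
    """Deduplicated (exact-coordinate) set of all fragments, NOT merged."""
    seen: dict[tuple[str, int, int], Region] = {}
    for p in pairs:
        for frag in (p.fragment_a, p.fragment_b):
            seen.setdefault((frag.chrom, frag.start, frag.end), frag)
    return sorted(seen.values(), key=lambda r: (r.chrom, r.start, r.end))


def summarize_segdup_pairs(
    pairs: Sequence[SegDupPair],
    identity_thresholds: Sequence[float] = (0.8, 0.9),
) -> PairSummary:
    """Identity, orientation and inter-chromosomal percentages of a pair table."""
    n = len(pairs)
    if n == 0:
        return PairSummary(0, {t: 0.0 for t in identity_thresholds}, 0.0, 0.0, 0)
    pct_gt = {
        t: round(100.0 * sum(p.identity > t for p in pairs) / n, 2)
        for t in identity_thresholds
    }
    pct_rev = round(100.0 * sum(not p.same_orientation for p in pairs) / n, 2)
    pct_inter = round(100.0 * sum(p.interchromosomal for p in pairs) / n, 2)
    return PairSummary(n, pct_gt, pct_rev, pct_inter, len(nonredundant_fragments(pairs)))


# -- TSV I/O ------------------------------------------------------------------

_COLUMNS = [
    "chromA",
    "startA",
    "endA",
    "chromB",
    "startB",
    "endB",
    "identity",
    "orientation",
]


def write_pair_table(pairs: Iterable[SegDupPair], path: str | Path) -> None:
    rows = [
        (
            p.fragment_a.chrom,
            p.fragment_a.start,
            p.fragment_a.end,
            p.fragment_b.chrom,
            p.fragment_b.start,
            p.fragment_b.end,
            f"{p.identity:.6f}",
            "same" if p.same_orientation else "reversed",
        )
        for p in pairs
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> list[SegDupPair]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair table {path} missing columns: {sorted(missing)}")
    return [
        SegDupPair(
            Region(str(r.chromA), int(r.startA), int(r.endA)),
            Region(str(r.chromB), int(r.startB), int(r.endB)),
            float(r.identity),
            str(r.orientation) == "same",
        )
        for r in df.itertuples(index=False)
    ]
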
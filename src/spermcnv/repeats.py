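"""Repeat annotations and repeat-content metrics for region sets.

For a target region set (SegDups, CNVs, or their flanks) and a repeat
annotation, the content of each repeat class is summarized as:

* ``length_bp``   — bp of repeat sequence intersecting the target footprint
  (a partially overlapping repeat contributes only its overlapped bp),
* ``count``       — number of repeat features overlapping the target
  (each feature counts once, however many target intervals it touches),
* ``avg_length``  — length_bp / count,
* ``length_pct``  — 100 * length_bp / target footprint bp, and
* ``count_per_mb``— count / (target footprint bp / 1e6).

Footprint denominators always use the *merged* target (union, not sum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeDef
from .regions import Region, _group_by_chrom, _merge_array

__all__ = [
    "RepeatFeature",
    "RepeatIndex",
    "repeat_content",
    "genome_repeat_content",
    "read_repeat_table",
    "write_repeat_table",
]

logger = logging.getLogger(__name__)

METRICS = ("avg_length", "length_pct", "count_per_mb")


@dataclass(frozen=True)
class RepeatFeature:
    """One repeat annotation interval (class plus family label)."""

    chrom: str
    start: int
    end: int
    repeat_class: str
    family: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


class RepeatIndex:
    """Per-class, per-chromosome sorted interval arrays for fast overlap."""

    def __init__(self, features: Iterable[RepeatFeature]):
        by_class: dict[str, list[RepeatFeature]] = {}
        for f in features:
            by_class.setdefault(f.repeat_class, []).append(f)
        self.classes: dict[str, dict[str, np.ndarray]] = {}
        self.class_total_bp: dict[str, int] = {}
        self.class_count: dict[str, int] = {}
        for cls, feats in by_class.items():
            grouped = _group_by_chrom(feats)
            self.classes[cls] = grouped
            self.class_total_bp[cls] = int(
                sum((arr[:, 1] - arr[:, 0]).sum() for arr in grouped.values())
            )
            self.class_count[cls] = len(feats)

    @property
    def class_names(self) -> list[str]:
        return sorted(self.classes)


def _target_arrays(target: Sequence) -> dict[str, np.ndarray]:
    return {c: _merge_array(arr, 0) for c, arr in _group_by_chrom(target).items()}


def _class_overlap(
    target: Mapping[str, np.ndarray], per_chrom: Mapping[str, np.ndarray]
) -> tuple[int, int]:
    """(bp of class intersecting target, number of class features touching it)."""
    bp = 0
    count = 0
    for chrom, t in target.items():
        r = per_chrom.get(chrom)
        if r is None or len(t) == 0:
            continue
        t_starts, t_ends = t[:, 0], t[:, 1]
        cum = np.concatenate([[0], np.cumsum(t_ends - t_starts)])
        lo = np.searchsorted(t_ends, r[:, 0], side="right")
        hi = np.searchsorted(t_starts, r[:, 1], side="left")
        hit = hi > lo
        if not hit.any():
            continue
        lo_h, hi_h = lo[hit], hi[hit]
        full = cum[hi_h] - cum[lo_h]
        left = np.maximum(0, r[hit, 0] - t_starts[lo_h])
        right = np.maximum(0, t_ends[hi_h - 1] - r[hit, 1])
        bp += int((full - left - right).sum())
        count += int(hit.sum())
    return bp, count


def _content_frame(
    target: Mapping[str, np.ndarray],
    index: RepeatIndex,
    classes: Sequence[str] | None,
) -> pd.DataFrame:
    names = list(classes) if classes is not None else index.class_names
    footprint = int(sum((t[:, 1] - t[:, 0]).sum() for t in target.values()))
    mb = footprint / 1e6
    rows = []
    for cls in names:
        per_chrom = index.classes.get(cls, {})
        bp, count = _class_overlap(target, per_chrom)
        rows.append(
            {
                "repeat_class": cls,
                "length_bp": bp,
                "count": count,
                "avg_length": bp / count if count else 0.0,
                "length_pct": 100.0 * bp / footprint if footprint else 0.0,
                "count_per_mb": count / mb if footprint else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["target_bp"] = footprint
    return df


def repeat_content(
    target: Sequence,
    repeats: RepeatIndex | Iterable[RepeatFeature],
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Repeat-content metrics of ``target`` per repeat class.

    ``target`` may be any region-like sequence; its merged footprint is the
    denominator.  An empty target yields all-zero rows (with a warning)
    rather than NaNs.
    """
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    arrays = _target_arrays(target)
    if not arrays:
        logger.warning("repeat_content called on an empty target; all metrics 0")
    return _content_frame(arrays, index, classes)


def genome_repeat_content(
    repeats: RepeatIndex | Iterable[RepeatFeature],
    genome: GenomeDef,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Whole-genome baseline metrics (target = every full chromosome)."""
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    whole = [Region(name, 0, length) for name, length in genome]
    return _content_frame(_target_arrays(whole), index, classes)


# -- I/O ----------------------------------------------------------------------

_COLUMNS = ["chrom", "start", "end", "repeat_class", "family"]


def write_repeat_table(features: Iterable[RepeatFeature], path: str | Path) -> None:
    """Write a RepeatMasker-style annotation table (TSV, 0-based half-open)."""
    rows = [(f.chrom, f.start, f.end, f.repeat_class, f.family) for f in features]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_repeat_table(path: str | Path) -> list[RepeatFeature]:
    df = pd.read_csv(path, sep="\t", dtype={"family": str}, keep_default_na=False)
    missing = set(_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"repeat table {path} missing columns: {sorted(missing)}")
    return [
        RepeatFeature(str(r.chrom), int(r.start), int(r.end), str(r.repeat_class),
                      str(getattr(r, "family", "")))
        for r in df.itertuples(index=False)
    ]
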
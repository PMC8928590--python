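"""Chromosome-arm positional distribution of SV events.

Cattle autosomes are acrocentric, so each chromosome is treated as a single
arm: an event's relative arm position is its midpoint divided by the
chromosome length (BND events use their single breakend position).  The
profile bins these fractions into 20 half-open 5% bins.

The terminal-enrichment test asks whether events concentrate near
chromosome ends.  Per chromosome, the terminal fraction (default 5%) at
each end is excluded outright; the two "end windows" are the next
``window`` bp (default 5 Mb) inward on each side; the remainder is the
interior.  End-window and interior event densities (events/Mb) are compared
across chromosomes with a paired two-sided Wilcoxon signed-rank test; a
pooled unpaired rank-sum test over per-window densities is reported as a
secondary statistic.  Chromosomes too short for the window layout are
skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeDef
from .variants import SVCall

__all__ = [
    "ArmProfile",
    "TerminalTestResult",
    "relative_positions",
    "bin_arm_distribution",
    "terminal_enrichment_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArmProfile:
    """Binned relative arm positions (20 bins of width 0.05 by default)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    group: str = "all"
    svtype: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "svtype": self.svtype,
                "group": self.group,
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class TerminalTestResult:
    """Wilcoxon comparison of end-window vs interior event densities."""

    svtype: str
    p_value: float                  # paired signed-rank across chromosomes
    p_value_pooled: float           # unpaired rank-sum over windows
    per_chromosome: pd.DataFrame    # chrom, end/interior counts and densities
    n_chromosomes: int


def relative_positions(calls: Sequence[SVCall], genome: GenomeDef) -> np.ndarray:
    """Midpoint / chromosome-length fraction in [0, 1) for each call."""
    out = np.empty(len(calls))
    for i, c in enumerate(calls):
        if c.chrom not in genome:
            raise KeyError(f"call on chromosome {c.chrom!r} absent from genome")
        out[i] = c.midpoint / genome.length_of(c.chrom)
    return out


def bin_arm_distribution(
    fractions: Sequence[float],
    bin_width: float = 0.05,
    group: str = "all",
    svtype: str = "all",
) -> ArmProfile:
    """Histogram of relative positions in half-open [k*w, (k+1)*w) bins."""
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    fractions = np.asarray(fractions, dtype=float)
    # np.histogram closes the last bin at 1.0, which is fine for fractions < 1
    counts, _ = np.histogram(fractions, bins=edges)
    return ArmProfile(edges, counts, group=group, svtype=svtype)


def _window_layout(
    length: int, terminal_frac: float, window: int
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None:
    """((left end win), (right end win), (interior)) or None if too short."""
    t = int(round(terminal_frac * length))
    if length < 2 * (t + window):
        return None
    left = (t, t + window)
    right = (length - t - window, length - t)
    interior = (t + window, length - t - window)
    if interior[0] >= interior[1]:
        return None
    return left, right, interior


def terminal_enrichment_test(
    calls: Sequence[SVCall],
    genome: GenomeDef,
    terminal_frac: float = 0.05,
    window: int = 5_000_000,
    svtype: str = "all",
) -> TerminalTestResult:
    """Test whether events are denser in chromosome-end windows than interiors."""
    if svtype != "all":
        calls = [c for c in calls if c.svtype == svtype]
    mids: dict[str, list[float]] = {}
    for c in calls:
        if c.chrom not in genome:
            raise KeyError(f"call on chromosome {c.chrom!r} absent from genome")
        mids.setdefault(c.chrom, []).append(c.midpoint)

    rows = []
    end_densities = []
    interior_densities = []
    pooled_end = []
    pooled_interior = []
    for name, length in genome:
        layout = _window_layout(length, terminal_frac, window)
        if layout is None:
            logger.warning(
                "chromosome %s (%.1f Mb) too short for terminal windows; skipped",
                name, length / 1e6,
            )
            continue
        (ls, le), (rs, re), (is_, ie) = layout
        pos = np.asarray(mids.get(name, []), dtype=float)
        n_left = int(((pos >= ls) & (pos < le)).sum())
        n_right = int(((pos >= rs) & (pos < re)).sum())
        n_interior = int(((pos >= is_) & (pos < ie)).sum())
        end_mb = 2 * window / 1e6
        interior_mb = (ie - is_) / 1e6
        d_end = (n_left + n_right) / end_mb
        d_int = n_interior / interior_mb
        rows.append(
            {
                "chrom": name,
                "n_end": n_left + n_right,
                "n_interior": n_interior,
                "end_mb": end_mb,
                "interior_mb": interior_mb,
                "density_end": d_end,
                "density_interior": d_int,
            }
        )
        end_densities.append(d_end)
        interior_densities.append(d_int)
        pooled_end += [n_left / (window / 1e6), n_right / (window / 1e6)]
        pooled_interior.append(d_int)

    if len(rows) < 2:
        raise ValueError("need >= 2 usable chromosomes for the terminal test")

    diffs = np.asarray(end_densities) - np.asarray(interior_densities)
    if np.all(diffs == 0):
        p_paired = 1.0
    else:
        p_paired = float(
            stats.wilcoxon(end_densities, interior_densities,
                           alternative="two-sided", zero_method="wilcox").pvalue
        )
    if np.ptp(pooled_end + pooled_interior) == 0:
        p_pooled = 1.0
    else:
        p_pooled = float(
            stats.mannwhitneyu(pooled_end, pooled_interior,
                               alternative="two-sided").pvalue
        )
    return TerminalTestResult(
        svtype=svtype,
        p_value=p_paired,
        p_value_pooled=p_pooled,
        per_chromosome=pd.DataFrame(rows),
        n_chromosomes=len(rows),
    )
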
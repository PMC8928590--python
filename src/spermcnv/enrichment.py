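"""Random-region permutation test for repeat-content enrichment.

The observed repeat-content metrics of a target region set are compared to
a null distribution obtained by repeatedly re-drawing the target at random
genomic positions, matched on region count and on mean/SD region length.
Lengths are drawn from a normal distribution truncated at >= 50 bp (a
resampling mode that permutes the observed lengths is also available);
chromosomes are chosen proportionally to their length, start positions
uniformly so the region fits, and random regions are allowed to overlap one
another.  The enrichment p-value is the fraction of null metric values
*strictly greater* than the observed value (ties therefore count toward
significance); the analogous strictly-less fraction is reported as a
depletion p-value.  With ``n_iter`` simulations the smallest attainable p
is 0, conventionally reported as "< 1/n_iter".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._rng import substream
from .genome import GenomeDef
from .regions import Region, _merge_array
from .repeats import (
    METRICS,
    RepeatFeature,
    RepeatIndex,
    _class_overlap,
    _content_frame,
    _target_arrays,
)

__all__ = ["EnrichmentResult", "random_region_set", "permutation_test", "results_frame"]

_MIN_LEN = 50


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs genome-baseline metric with its permutation null."""

    repeat_class: str
    metric: str
    observed: float
    genome_baseline: float
    fold: float
    null_values: np.ndarray
    p_value: float          # enrichment: frac(null > observed)
    p_depletion: float      # depletion:  frac(null < observed)

    @property
    def n_iter(self) -> int:
        return len(self.null_values)

    def p_label(self) -> str:
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_iter:g}"
        return f"{self.p_value:.3g}"


def _draw_lengths(
    rng: np.random.Generator,
    n: int,
    mean_len: float,
    sd_len: float,
    observed_lengths: np.ndarray | None,
    mode: str,
) -> np.ndarray:
    if mode == "resample":
        if observed_lengths is None or len(observed_lengths) == 0:
            raise ValueError("resample length mode requires observed lengths")
        return rng.choice(observed_lengths, size=n, replace=True).astype(np.int64)
    if sd_len <= 0:
        return np.full(n, max(_MIN_LEN, int(round(mean_len))), dtype=np.int64)
    # normal truncated at >= _MIN_LEN, sampled by inverse CDF
    lo = ndtr((_MIN_LEN - mean_len) / sd_len)
    u = lo + rng.random(n) * (1.0 - lo)
    vals = mean_len + sd_len * ndtri(u)
    return np.maximum(np.round(vals).astype(np.int64), _MIN_LEN)


def _random_arrays(
    genome: GenomeDef,
    n: int,
    mean_len: float,
    sd_len: float,
    rng: np.random.Generator,
    exclude: Mapping[str, np.ndarray] | None = None,
    observed_lengths: np.ndarray | None = None,
    length_mode: str = "normal",
    max_retries: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(chrom index, start, end) arrays of a random region set."""
    names = np.asarray(genome.names)
    lengths = np.asarray([l for _, l in genome.chromosomes], dtype=np.float64)
    probs = lengths / lengths.sum()
    region_len = _draw_lengths(rng, n, mean_len, sd_len, observed_lengths, length_mode)
    chrom_idx = rng.choice(len(names), size=n, p=probs)
    space = lengths[chrom_idx] - region_len
    starts = np.where(space >= 0, np.floor(rng.random(n) * (space + 1)), -1).astype(np.int64)

    def _ok(ci: int, s: int, e: int) -> bool:
        if s < 0:
            return False
        if exclude:
            ex = exclude.get(str(names[ci]))
            if ex is not None and len(ex):
                j = np.searchsorted(ex[:, 1], s, side="right")
                if j < len(ex) and ex[j, 0] < e:
                    return False
        return True

    for i in range(n):
        if _ok(chrom_idx[i], starts[i], starts[i] + region_len[i]):
            continue
        placed = False
        for _ in range(max_retries):
            ci = rng.choice(len(names), p=probs)
            space_i = lengths[ci] - region_len[i]
            if space_i < 0:
                continue
            s = int(rng.integers(0, int(space_i) + 1))
            if _ok(ci, s, s + region_len[i]):
                chrom_idx[i], starts[i] = ci, s
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a random region of length {region_len[i]} "
                f"after {max_retries} retries (genome too small or exclude "
                "set too dense)"
            )
    return chrom_idx, starts, starts + region_len


def random_region_set(
    genome: GenomeDef,
    n: int,
    mean_len: float,
    sd_len: float,
    seed: int | np.random.Generator = 0,
    exclude: Sequence | None = None,
    length_mode: str = "normal",
    observed_lengths: Sequence[int] | None = None,
) -> list[Region]:
    """Draw ``n`` random regions matched to a length distribution.

    See the module docstring for the placement model.  ``exclude`` regions
    are avoided by rejection sampling (at most 1,000 retries per region).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_len <= 0:
        raise ValueError("mean_len must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "random-regions")
    ex = _target_arrays(exclude) if exclude else None
    obs = None if observed_lengths is None else np.asarray(observed_lengths, dtype=np.int64)
    ci, s, e = _random_arrays(genome, n, mean_len, sd_len, rng, ex, obs, length_mode)
    names = genome.names
    return [Region(names[c], int(a), int(b)) for c, a, b in zip(ci, s, e)]


def permutation_test(
    target: Sequence,
    repeats: RepeatIndex | Sequence[RepeatFeature],
    genome: GenomeDef,
    n_iter: int = 1000,
    seed: int = 0,
    metrics: Sequence[str] = METRICS,
    classes: Sequence[str] | None = None,
    exclude: Sequence | None = None,
    length_mode: str = "normal",
) -> list[EnrichmentResult]:
    """Permutation enrichment test of target repeat content, per class x metric.

    Each iteration re-draws the target (same n, mean and SD of region
    lengths) at random genomic positions and recomputes the metrics.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    bad = set(metrics) - set(METRICS)
    if bad:
        raise ValueError(f"unknown metrics: {sorted(bad)}")
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    cls_names = list(classes) if classes is not None else index.class_names

    target = list(target)
    obs_lengths = np.asarray([r.end - r.start for r in target], dtype=np.int64)
    if len(obs_lengths) == 0:
        raise ValueError("empty target region set")
    n = len(obs_lengths)
    mean_len = float(obs_lengths.mean())
    sd_len = float(obs_lengths.std(ddof=0))

    observed = _content_frame(_target_arrays(target), index, cls_names)
    baseline = _content_frame(
        _target_arrays([Region(c, 0, l) for c, l in genome]), index, cls_names
    )
    ex = _target_arrays(exclude) if exclude else None

    null = {
        (cls, m): np.empty(n_iter) for cls in cls_names for m in metrics
    }
    names = genome.names
    for it in range(n_iter):
        rng = substream(seed, "perm", it)
        ci, s, e = _random_arrays(genome, n, mean_len, sd_len, rng, ex,
                                  obs_lengths, length_mode)
        arrays: dict[str, np.ndarray] = {}
        for c in np.unique(ci):
            sel = ci == c
            arr = np.column_stack([s[sel], e[sel]])
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            arrays[names[c]] = _merge_array(arr, 0)
        footprint = int(sum((t[:, 1] - t[:, 0]).sum() for t in arrays.values()))
        for cls in cls_names:
            bp, count = _class_overlap(arrays, index.classes.get(cls, {}))
            vals = {
                "avg_length": bp / count if count else 0.0,
                "length_pct": 100.0 * bp / footprint if footprint else 0.0,
                "count_per_mb": count / (footprint / 1e6) if footprint else 0.0,
            }
            for m in metrics:
                null[(cls, m)][it] = vals[m]

    results: list[EnrichmentResult] = []
    for i, cls in enumerate(cls_names):
        for m in metrics:
            obs_val = float(observed.iloc[i][m])
            base_val = float(baseline.iloc[i][m])
            nulls = null[(cls, m)]
            results.append(
                EnrichmentResult(
                    repeat_class=cls,
                    metric=m,
                    observed=obs_val,
                    genome_baseline=base_val,
                    fold=obs_val / base_val if base_val else float("nan"),
                    null_values=nulls,
                    p_value=float(np.mean(nulls > obs_val)),
                    p_depletion=float(np.mean(nulls < obs_val)),
                )
            )
    return results


def results_frame(results: Sequence[EnrichmentResult], seed: int | None = None) -> pd.DataFrame:
    """Flatten results into the TSV report layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "repeat_class": r.repeat_class,
                "metric": r.metric,
                "observed": r.observed,
                "genome_baseline": r.genome_baseline,
                "fold": r.fold,
                "p_enrich": r.p_value,
                "p_deplete": r.p_depletion,
                "n_iter": r.n_iter,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
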
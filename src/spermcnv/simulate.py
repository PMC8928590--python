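"""Synthetic inputs for the whole pipeline: genome, repeats, SegDup pairs,
and multi-sample SV call sets with planted, parameterized structure.

The generator emulates a single-sperm CNV study design: two groups of
haploid sperm cells from two bulls plus one diploid family-trio group, with

* a configurable **sharing profile** — how many non-singleton CNV events
  fall in each of the 7 Venn categories over the three groups,
* **distal bias** — probability mass placed in the terminal 5% of
  chromosomes (subtelomeric CNV concentration),
* **satellite co-location** — probability that a CNV midpoint lands inside
  a satellite repeat block, and
* per-sample fold coverage driving the support-read filter, with a
  configurable fraction of background calls passing it.

Every planted event is recorded in a truth table (Venn category, singleton
status, distal / satellite placement, and per-call filter pass flags), so
downstream modules can be verified against known ground truth.  All draws
come from sub-streams keyed by (stage, sample) of a single master seed, so
outputs are byte-identical across runs and adding a sample does not shift
the draws of earlier stages.

Planted events are mutually non-overlapping; calls for one shared event are
placed at identical coordinates in every carrying sample unless
``coord_jitter_bp`` is set.  Shared (non-singleton) events always receive
filter-passing support counts — they model confidently detected variants —
while background singletons pass with probability
``support_pass_fraction``.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .genome import GenomeDef
from .repeats import RepeatFeature, write_repeat_table
from .regions import write_bed, Region
from .segdup import SegDupPair, write_pair_table
from .variants import SVCall, FilterPolicy, write_sv_vcf, write_coverage_table
from .sharing import venn_category

__all__ = [
    "GROUP_S1",
    "GROUP_S2",
    "GROUP_TRIO",
    "DEMO_SHARING_PROFILE",
    "SimulationConfig",
    "SimulatedCallsets",
    "generate_genome",
    "generate_repeats",
    "generate_segdup_pairs",
    "generate_callsets",
    "write_simulation",
]

GROUP_S1 = "Sample1-sperms"
GROUP_S2 = "Sample2-sperms"
GROUP_TRIO = "Sample1-trio"
GROUPS = (GROUP_S1, GROUP_S2, GROUP_TRIO)

# The worked-example sharing profile: 433 non-singleton DEL/DUP events
# split over the 7 Venn categories of the three groups.
DEMO_SHARING_PROFILE: dict[str, int] = {
    venn_category([GROUP_S1, GROUP_S2, GROUP_TRIO]): 18,
    venn_category([GROUP_S1, GROUP_TRIO]): 45,
    venn_category([GROUP_S1, GROUP_S2]): 158,
    venn_category([GROUP_S2, GROUP_TRIO]): 18,
    venn_category([GROUP_S1]): 123,
    venn_category([GROUP_S2]): 56,
    venn_category([GROUP_TRIO]): 15,
}

# Typical feature length (bp) per repeat class, used to size synthetic
# annotation features; satellite blocks are long tandem arrays.
_CLASS_MEAN_LEN: dict[str, int] = {
    "LINE": 3000,
    "SINE": 200,
    "LTR": 1000,
    "DNA": 600,
    "Satellite": 8000,
    "Simple_repeat": 120,
}
_DEFAULT_MEAN_LEN = 600


def _default_densities() -> dict[str, float]:
    # roughly mammalian-like class fractions of the genome
    return {"LINE": 0.23, "SINE": 0.15, "LTR": 0.04, "DNA": 0.02, "Satellite": 0.02}


def _default_samples() -> dict[str, int]:
    # deep-coverage sperm subsets of each bull plus the 3 trio genomes
    return {GROUP_S1: 8, GROUP_S2: 6, GROUP_TRIO: 3}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults emulate the study design."""

    n_chromosomes: int = 29
    chrom_length_range: tuple[int, int] = (42_000_000, 158_000_000)
    repeat_class_densities: dict[str, float] = field(default_factory=_default_densities)
    segdup_pair_count: int = 1000
    segdup_identity_mean: float = 0.80
    segdup_identity_sd: float = 0.10
    segdup_interchrom_prob: float = 0.60
    segdup_reversed_prob: float = 0.63
    segdup_fragment_mean_len: int = 2000
    cnv_counts_per_sample: int = 50
    inv_per_sample: int = 5
    bnd_per_sample: int = 10
    event_length_range: tuple[int, int] = (50, 5_000_000)
    distal_bias: float = 0.3
    terminal_frac: float = 0.05
    # distal placement zone = terminal `terminal_frac` of the chromosome
    # plus this many bp further inward; 0 restricts the zone to the strict
    # terminal fraction.  The default matches the 5 Mb end windows of the
    # terminal-enrichment test, so planted distal events model the broad
    # subtelomeric CNV concentration that such a test can observe.
    distal_window_bp: int = 5_000_000
    satellite_colocation_prob: float = 0.2
    satellite_class: str = "Satellite"
    sharing_profile: dict[str, int] = field(
        default_factory=lambda: dict(DEMO_SHARING_PROFILE)
    )
    samples_per_group: dict[str, int] = field(default_factory=_default_samples)
    per_sample_coverage: dict[str, float] | None = None
    support_pass_fraction: float = 0.9
    coord_jitter_bp: int = 0
    include_length_boundaries: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        lo, hi = self.chrom_length_range
        if lo > hi:
            errs.append(f"chrom_length_range min {lo} > max {hi}")
        if lo <= 0:
            errs.append("chromosome lengths must be > 0")
        if self.n_chromosomes < 1:
            errs.append("n_chromosomes must be >= 1")
        for name, p in [
            ("distal_bias", self.distal_bias),
            ("satellite_colocation_prob", self.satellite_colocation_prob),
            ("support_pass_fraction", self.support_pass_fraction),
            ("segdup_interchrom_prob", self.segdup_interchrom_prob),
            ("segdup_reversed_prob", self.segdup_reversed_prob),
            ("terminal_frac", self.terminal_frac),
        ]:
            if not 0.0 <= p <= 1.0:
                errs.append(f"{name}={p} outside [0, 1]")
        dens = self.repeat_class_densities
        if any(d < 0 for d in dens.values()):
            errs.append("negative repeat density")
        if sum(dens.values()) > 1.0 + 1e-9:
            errs.append(f"repeat densities sum to {sum(dens.values()):.3f} > 1")
        for name, n in [
            ("segdup_pair_count", self.segdup_pair_count),
            ("cnv_counts_per_sample", self.cnv_counts_per_sample),
            ("inv_per_sample", self.inv_per_sample),
            ("bnd_per_sample", self.bnd_per_sample),
            ("coord_jitter_bp", self.coord_jitter_bp),
        ]:
            if n < 0:
                errs.append(f"{name} must be >= 0")
        if any(v < 0 for v in self.sharing_profile.values()):
            errs.append("negative sharing_profile count")
        canonical: dict[str, int] = {}
        for key, count in self.sharing_profile.items():
            groups = key.split("&")
            if not set(groups) <= set(GROUPS):
                errs.append(f"unknown sharing_profile category {key!r}")
                continue
            cat = venn_category(groups)
            canonical[cat] = canonical.get(cat, 0) + count
        self.sharing_profile = canonical
        el, eh = self.event_length_range
        if not (0 < el <= eh):
            errs.append(f"invalid event_length_range ({el}, {eh})")
        if errs:
            raise ValueError("invalid simulation config: " + "; ".join(errs))

    # -- samples --------------------------------------------------------------

    def sample_ids(self, group: str) -> list[str]:
        n = self.samples_per_group.get(group, 0)
        if group == GROUP_TRIO:
            names = ["Sample1-diploid", "Sample1-sire", "Sample1-dam"]
            return names[:n] + [f"trio_extra_{i}" for i in range(len(names), n)]
        tag = "S1_sperm" if group == GROUP_S1 else "S2_sperm"
        return [f"{tag}_{i + 1:02d}" for i in range(n)]

    def coverage_map(self) -> dict[str, float]:
        if self.per_sample_coverage is not None:
            return dict(self.per_sample_coverage)
        cov: dict[str, float] = {}
        for s in self.sample_ids(GROUP_S1) + self.sample_ids(GROUP_S2):
            cov[s] = 4.0  # deep single-sperm coverage
        trio_defaults = {"Sample1-diploid": 40.0, "Sample1-sire": 10.0,
                         "Sample1-dam": 20.0}
        for s in self.sample_ids(GROUP_TRIO):
            cov[s] = trio_defaults.get(s, 20.0)
        return cov

    # -- YAML round trip ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["chrom_length_range"] = list(self.chrom_length_range)
        data["event_length_range"] = list(self.event_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("chrom_length_range", "event_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# -- Genome -------------------------------------------------------------------


def generate_genome(config: SimulationConfig) -> GenomeDef:
    """Draw chromosome lengths uniformly within the configured range."""
    rng = substream(config.seed, "genome")
    lo, hi = config.chrom_length_range
    lengths = rng.integers(int(lo), int(hi) + 1, size=config.n_chromosomes)
    return GenomeDef(
        tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(lengths))
    )


# -- Repeats ------------------------------------------------------------------


def generate_repeats(
    genome: GenomeDef, config: SimulationConfig
) -> list[RepeatFeature]:
    """Place non-overlapping features per class at the requested densities.

    Each chromosome is divided into per-class slots; one feature is placed
    inside each slot, so features of a class never overlap and the realized
    genome fraction tracks the requested density closely.
    """
    out: list[RepeatFeature] = []
    for cls in sorted(config.repeat_class_densities):
        density = config.repeat_class_densities[cls]
        if density <= 0:
            continue
        rng = substream(config.seed, "repeats", cls)
        mean_len = _CLASS_MEAN_LEN.get(cls, _DEFAULT_MEAN_LEN)
        fam_counter = 0
        for chrom, length in genome:
            target_bp = density * length
            n = max(1, int(round(target_bp / mean_len)))
            lens = rng.normal(mean_len, 0.3 * mean_len, size=n)
            lens = np.clip(lens, 0.2 * mean_len, 3.0 * mean_len)
            lens = np.maximum(np.round(lens * (target_bp / lens.sum())), 1).astype(int)
            slot = length / n
            for i in range(n):
                l = int(min(lens[i], math.floor(slot)))
                s0 = int(math.floor(i * slot))
                s1 = int(math.floor((i + 1) * slot)) - l
                start = int(rng.integers(s0, max(s0, s1) + 1))
                out.append(
                    RepeatFeature(chrom, start, start + l, cls,
                                  f"{cls}_fam{fam_counter % 3 + 1}")
                )
                fam_counter += 1
    out.sort(key=lambda f: (f.chrom, f.start, f.repeat_class))
    return out


# -- SegDup pairs -------------------------------------------------------------


def generate_segdup_pairs(
    genome: GenomeDef, config: SimulationConfig
) -> list[SegDupPair]:
    """Draw pairwise SegDup fragments with configured identity/orientation."""
    rng = substream(config.seed, "segdup")
    names = genome.names
    lengths = np.asarray([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    pairs: list[SegDupPair] = []
    mean = config.segdup_fragment_mean_len
    for _ in range(config.segdup_pair_count):
        frag_len = max(100, int(rng.lognormal(math.log(mean) - 0.18, 0.6)))
        ia = rng.choice(len(names), p=probs)
        if rng.random() < config.segdup_interchrom_prob and len(names) > 1:
            others = np.delete(np.arange(len(names)), ia)
            p = probs[others] / probs[others].sum()
            ib = int(rng.choice(others, p=p))
        else:
            ib = int(ia)
        frags = []
        for ci in (int(ia), ib):
            l = min(frag_len, int(lengths[ci]))
            start = int(rng.integers(0, int(lengths[ci]) - l + 1))
            frags.append(Region(names[ci], start, start + l))
        if config.segdup_identity_sd <= 0:
            ident = config.segdup_identity_mean
        else:
            ident = float(
                rng.normal(config.segdup_identity_mean, config.segdup_identity_sd)
            )
        ident = min(1.0, max(1e-6, ident))  # truncate to (0, 1]
        pairs.append(
            SegDupPair(frags[0], frags[1], ident,
                       same_orientation=rng.random() >= config.segdup_reversed_prob)
        )
    return pairs


# -- Call sets ----------------------------------------------------------------


@dataclass
class SimulatedCallsets:
    """All call sets plus planted truth."""

    calls_by_sample: dict[str, list[SVCall]]
    group_of_sample: dict[str, str]
    coverage: dict[str, float]
    events: pd.DataFrame   # one row per planted event
    calls: pd.DataFrame    # one row per emitted VCF record

    def all_calls(self) -> list[SVCall]:
        out: list[SVCall] = []
        for sample in sorted(self.calls_by_sample):
            out.extend(self.calls_by_sample[sample])
        return out


class _Occupancy:
    """Sorted disjoint intervals per chromosome, for rejection placement."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return True
        i = bisect.bisect_right(starts, start)
        if i > 0 and self._ends[chrom][i - 1] > start:
            return False
        if i < len(starts) and starts[i] < end:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_right(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _passing_support(rng: np.random.Generator, coverage: float,
                     policy: FilterPolicy) -> tuple[int, int]:
    primary = policy.coverage_fraction * coverage
    if rng.random() < 0.5:  # paired-end as primary signal
        pe = math.floor(primary) + 1 + int(rng.poisson(2))
        sr = policy.secondary_sr_min + 1 + int(rng.poisson(1))
    else:                   # split-read as primary signal
        sr = math.floor(primary) + 1 + int(rng.poisson(2))
        pe = policy.secondary_pe_min + 1 + int(rng.poisson(1))
    return pe, sr


def _failing_support(rng: np.random.Generator,
                     policy: FilterPolicy) -> tuple[int, int]:
    # both disjuncts fail for any coverage: PE <= secondary_pe_min kills the
    # SR-primary branch, SR <= secondary_sr_min kills the PE-primary branch
    pe = int(rng.integers(0, policy.secondary_pe_min + 1))
    sr = int(rng.integers(0, policy.secondary_sr_min + 1))
    return pe, sr


def _draw_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _place_event(
    rng: np.random.Generator,
    genome: GenomeDef,
    length: int,
    config: SimulationConfig,
    satellites: Sequence[RepeatFeature],
    occupancy: _Occupancy,
    max_tries: int = 1000,
) -> tuple[str, int, bool, bool]:
    """Choose (chrom, start, placed_distal, placed_in_satellite) for an event."""
    names = genome.names
    lengths = np.asarray([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    tf = config.terminal_frac
    for _ in range(max_tries):
        u = rng.random()
        distal = u < config.distal_bias
        satellite = (not distal) and (
            rng.random() < config.satellite_colocation_prob and len(satellites) > 0
        )
        if distal:
            # midpoint uniform within the distal zone, guaranteed inside it
            zone = lengths * tf + config.distal_window_bp
            fits = np.nonzero(np.minimum(zone, lengths / 2) > length / 2 + 1)[0]
            if len(fits) == 0:
                if config.distal_bias >= 1.0:
                    raise RuntimeError(
                        f"no chromosome can hold a {length} bp event within "
                        f"its distal zone (terminal {tf:.0%} + "
                        f"{config.distal_window_bp} bp)"
                    )
                distal = False  # too long for any distal zone; place freely
        if distal:
            p = probs[fits] / probs[fits].sum()
            ci = int(rng.choice(fits, p=p))
            L = int(lengths[ci])
            half = length / 2
            win_lo, win_hi = half, min(zone[ci], L / 2)
            m = rng.uniform(win_lo, win_hi)
            if rng.random() < 0.5:
                m = L - m
            start = int(round(m - half))
            start = min(max(start, 0), L - length)
        elif satellite:
            f = satellites[int(rng.integers(0, len(satellites)))]
            L = genome.length_of(f.chrom)
            if length > L:
                continue
            m = rng.uniform(f.start, f.end)
            start = int(round(m - length / 2))
            start = min(max(start, 0), L - length)
            mid = start + length / 2
            if not (f.start <= mid < f.end):
                continue
            ci = list(names).index(f.chrom)
        else:
            fits = np.nonzero(lengths >= length)[0]
            if len(fits) == 0:
                raise RuntimeError(
                    f"event of length {length} exceeds every chromosome"
                )
            p = probs[fits] / probs[fits].sum()
            ci = int(rng.choice(fits, p=p))
            start = int(rng.integers(0, int(lengths[ci]) - length + 1))
        chrom = names[ci]
        if occupancy.is_free(chrom, start, start + length):
            occupancy.add(chrom, start, start + length)
            return chrom, start, distal, satellite
    raise RuntimeError(
        f"could not place a {length} bp event after {max_tries} attempts; "
        "genome too crowded for the requested event counts"
    )


def generate_callsets(
    genome: GenomeDef,
    repeats: Sequence[RepeatFeature],
    config: SimulationConfig,
    policy: FilterPolicy = FilterPolicy(),
) -> SimulatedCallsets:
    """Plant shared events per the sharing profile plus per-sample background.

    Returns per-sample call lists, the coverage map, and two truth tables:
    one row per planted event (category, singleton/distal/satellite flags,
    union and summed lengths) and one per emitted call (support counts and
    filter pass flags).
    """
    satellites = [f for f in repeats if f.repeat_class == config.satellite_class]
    occupancy = _Occupancy()
    ev_rng = substream(config.seed, "events")
    lo, hi = config.event_length_range

    group_of_sample: dict[str, str] = {}
    calls_by_sample: dict[str, list[SVCall]] = {}
    for group in GROUPS:
        for s in config.sample_ids(group):
            group_of_sample[s] = group
            calls_by_sample[s] = []
    coverage = config.coverage_map()
    missing_cov = set(group_of_sample) - set(coverage)
    if missing_cov:
        raise ValueError(f"no coverage configured for samples: {sorted(missing_cov)}")

    support_rng = {s: substream(config.seed, "support", s) for s in group_of_sample}

    event_rows: list[dict] = []
    call_rows: list[dict] = []
    ev_counter = 0

    def emit_call(sample: str, event_id: str, svtype: str, chrom: str,
                  start: int, end: int, force_pass: bool | None) -> None:
        rng = support_rng[sample]
        cov = coverage[sample]
        if config.coord_jitter_bp > 0:
            j = config.coord_jitter_bp
            start = max(0, start + int(rng.integers(-j, j + 1)))
            end = min(genome.length_of(chrom), end + int(rng.integers(-j, j + 1)))
            if end <= start:
                end = start + 1
        if force_pass is None:
            force_pass = rng.random() < config.support_pass_fraction
        if force_pass:
            pe, sr = _passing_support(rng, cov, policy)
        else:
            pe, sr = _failing_support(rng, policy)
        length = end - start if svtype != "BND" else None
        passes_len = (
            svtype not in ("DEL", "DUP")
            or policy.min_len <= length <= policy.max_len
        )
        call_id = f"{event_id}.{sample}"
        calls_by_sample[sample].append(
            SVCall(sample, group_of_sample[sample], svtype, chrom, start,
                   end, pe, sr, call_id)
        )
        call_rows.append(
            {
                "call_id": call_id,
                "sample_id": sample,
                "group": group_of_sample[sample],
                "event_id": event_id,
                "svtype": svtype,
                "chrom": chrom,
                "start": start,
                "end": end,
                "pe": pe,
                "sr": sr,
                "passes_length": passes_len,
                "passes_support": bool(force_pass),
                "passes_all": passes_len and bool(force_pass),
            }
        )

    def record_event(event_id: str, svtype: str, chrom: str, start: int,
                     end: int, category: str, singleton: bool,
                     distal: bool, satellite: bool,
                     first_call_idx: int) -> None:
        members = call_rows[first_call_idx:]
        starts = [m["start"] for m in members]
        ends = [m["end"] for m in members]
        union = max(ends) - min(starts) if members else end - start
        total = sum(m["end"] - m["start"] for m in members)
        event_rows.append(
            {
                "event_id": event_id,
                "svtype": svtype,
                "chrom": chrom,
                "start": start,
                "end": end,
                "venn_category": category,
                "is_singleton": singleton,
                "placed_distal": distal,
                "placed_in_satellite": satellite,
                "n_member_calls": len(members),
                "length_union_bp": union,
                "length_sum_bp": total,
            }
        )

    # --- shared (non-singleton) events per the sharing profile ---------------
    for category in sorted(config.sharing_profile):
        count = config.sharing_profile[category]
        cat_groups = category.split("&")
        for _ in range(count):
            svtype = "DEL" if ev_rng.random() < 0.5 else "DUP"
            length = _draw_length(ev_rng, lo, hi)
            chrom, start, distal, sat = _place_event(
                ev_rng, genome, length, config, satellites, occupancy
            )
            event_id = f"ev{ev_counter:05d}"
            ev_counter += 1
            first_idx = len(call_rows)
            for group in GROUPS:
                if group not in cat_groups:
                    continue
                samples = config.sample_ids(group)
                if len(cat_groups) == 1:
                    if len(samples) < 2:
                        raise ValueError(
                            f"group {group} needs >= 2 samples to host "
                            "single-group non-singleton events"
                        )
                    chosen = [samples[i] for i in
                              sorted(ev_rng.choice(len(samples), 2, replace=False))]
                else:
                    chosen = [samples[int(ev_rng.integers(0, len(samples)))]]
                for s in chosen:
                    emit_call(s, event_id, svtype, chrom, start,
                              start + length, force_pass=True)
            record_event(event_id, svtype, chrom, start, start + length,
                         category, False, distal, sat, first_idx)

    # --- per-sample background singletons ------------------------------------
    ordered_samples = sorted(group_of_sample)
    for sample in ordered_samples:
        bg_rng = substream(config.seed, "background", sample)
        # boundary-length probes go on the first sample, placed before the
        # background so multi-Mb events still find room
        n_boundary = 4 if (config.include_length_boundaries
                           and sample == ordered_samples[0]) else 0
        for k in range(config.cnv_counts_per_sample + n_boundary):
            svtype = "DEL" if bg_rng.random() < 0.5 else "DUP"
            if k < n_boundary:
                length = (49, 50, 5_000_000, 5_000_001)[k]
            else:
                length = _draw_length(bg_rng, lo, hi)
            chrom, start, distal, sat = _place_event(
                bg_rng, genome, length, config, satellites, occupancy
            )
            event_id = f"ev{ev_counter:05d}"
            ev_counter += 1
            first_idx = len(call_rows)
            emit_call(sample, event_id, svtype, chrom, start, start + length,
                      force_pass=None)
            record_event(event_id, svtype, chrom, start, start + length,
                         venn_category([group_of_sample[sample]]), True,
                         distal, sat, first_idx)
        # inversions
        for _ in range(config.inv_per_sample):
            length = _draw_length(bg_rng, lo, min(hi, 500_000))
            chrom, start, distal, sat = _place_event(
                bg_rng, genome, length, config, satellites, occupancy
            )
            event_id = f"ev{ev_counter:05d}"
            ev_counter += 1
            first_idx = len(call_rows)
            emit_call(sample, event_id, "INV", chrom, start, start + length,
                      force_pass=None)
            record_event(event_id, "INV", chrom, start, start + length,
                         venn_category([group_of_sample[sample]]), True,
                         distal, sat, first_idx)
        # breakends, emitted as mated pairs where possible
        bnd_ids: list[str] = []
        for _ in range(config.bnd_per_sample):
            chrom, start, distal, sat = _place_event(
                bg_rng, genome, 1, config, satellites, occupancy
            )
            event_id = f"ev{ev_counter:05d}"
            ev_counter += 1
            first_idx = len(call_rows)
            emit_call(sample, event_id, "BND", chrom, start, start + 1,
                      force_pass=None)
            record_event(event_id, "BND", chrom, start, start + 1,
                         venn_category([group_of_sample[sample]]), True,
                         distal, sat, first_idx)
            bnd_ids.append(f"{event_id}.{sample}")
        # pair consecutive breakends
        by_id = {c.call_id: c for c in calls_by_sample[sample]}
        for a, b in zip(bnd_ids[0::2], bnd_ids[1::2]):
            for x, y in ((a, b), (b, a)):
                c = by_id[x]
                calls_by_sample[sample][calls_by_sample[sample].index(c)] = SVCall(
                    c.sample_id, c.group, c.svtype, c.chrom, c.start, c.end,
                    c.pe_support, c.sr_support, c.call_id, mate_id=y,
                )

    events = pd.DataFrame(event_rows)
    calls = pd.DataFrame(call_rows)
    return SimulatedCallsets(calls_by_sample, group_of_sample, coverage,
                             events, calls)


# -- Full simulation bundle ---------------------------------------------------


def write_simulation(
    outdir: str | Path,
    config: SimulationConfig,
    genome: GenomeDef,
    repeats: Sequence[RepeatFeature],
    segdups: Sequence[SegDupPair],
    callsets: SimulatedCallsets,
) -> dict[str, Path]:
    """Write every simulated input in its on-disk dialect; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    genome.write_chrom_sizes(paths["chrom_sizes"])
    paths["repeats_tsv"] = outdir / "repeats.tsv"
    write_repeat_table(repeats, paths["repeats_tsv"])
    paths["repeats_bed"] = outdir / "repeats.bed"
    write_bed(
        [Region(f.chrom, f.start, f.end, {"name": f.repeat_class}) for f in repeats],
        paths["repeats_bed"],
        name_key="name",
    )
    paths["segdup_pairs"] = outdir / "segdup_pairs.tsv"
    write_pair_table(segdups, paths["segdup_pairs"])
    paths["coverage"] = outdir / "coverage.tsv"
    write_coverage_table(callsets.coverage, paths["coverage"])
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample in sorted(callsets.calls_by_sample):
        p = vcf_dir / f"{sample}.vcf"
        write_sv_vcf(callsets.calls_by_sample[sample], genome, p)
        paths[f"vcf:{sample}"] = p
    paths["truth_events"] = outdir / "truth_events.tsv"
    callsets.events.to_csv(paths["truth_events"], sep="\t", index=False)
    paths["truth_calls"] = outdir / "truth_calls.tsv"
    callsets.calls.to_csv(paths["truth_calls"], sep="\t", index=False)
    paths["config"] = outdir / "sim_config.yaml"
    config.to_yaml(paths["config"])
    return paths
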
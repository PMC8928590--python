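"""Structural-variant calls: VCF parsing, quality filters, group tallies.

Calls are consumed from single-sample SV VCFs in the dialect produced by
paired-end/split-read callers (INFO keys SVTYPE, END, SVLEN, PE, SR).  Two
filters reproduce the standard single-sperm CNV cleaning:

* a length filter keeping DEL/DUP of 50 bp – 5 Mb (bounds inclusive;
  INV/BND are not length-filtered), and
* a support filter requiring, at a sample of fold-coverage ``c``, that one
  evidence type (paired-end or split-read read count) exceeds ``0.75 * c``
  while the other exceeds its secondary minimum (SR > 1 when PE is the
  primary signal, PE > 3 when SR is).  All comparisons are strict and the
  0.75·c threshold is kept real-valued.

Coordinates are converted to 0-based half-open on input (VCF POS=101,
END=200 becomes [100, 200), length 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

from .genome import GenomeDef
from .regions import covered_bp

__all__ = [
    "SVTYPES",
    "CNV_TYPES",
    "SVCall",
    "FilterPolicy",
    "parse_sv_vcf",
    "filter_by_length",
    "filter_by_support",
    "tally_by_group",
    "read_coverage_table",
    "write_coverage_table",
    "write_sv_vcf",
]

logger = logging.getLogger(__name__)

SVTYPES = ("BND", "DEL", "DUP", "INV")
CNV_TYPES = ("DEL", "DUP")
_INTERVAL_TYPES = ("DEL", "DUP", "INV")


@dataclass(frozen=True)
class SVCall:
    """One structural-variant record.

    ``start``/``end`` are 0-based half-open.  For BND records ``end`` is
    ``start + 1`` (the single breakend position) and ``length`` is None.
    """

    sample_id: str
    group: str
    svtype: str
    chrom: str
    start: int
    end: int
    pe_support: int
    sr_support: int
    call_id: str | None = None
    mate_id: str | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svtype in _INTERVAL_TYPES and not self.start < self.end:
            raise ValueError(
                f"{self.svtype} call {self.chrom}:{self.start}-{self.end} "
                "needs start < end"
            )
        if self.pe_support < 0 or self.sr_support < 0:
            raise ValueError("negative support counts")

    @property
    def length(self) -> int | None:
        return self.end - self.start if self.svtype in _INTERVAL_TYPES else None

    @property
    def midpoint(self) -> float:
        if self.svtype == "BND":
            return float(self.start)
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class FilterPolicy:
    """Length and support-read filter thresholds."""

    min_len: int = 50
    max_len: int = 5_000_000
    coverage_fraction: float = 0.75
    secondary_sr_min: int = 1
    secondary_pe_min: int = 3

    def __post_init__(self) -> None:
        if not self.min_len < self.max_len:
            raise ValueError("min_len must be < max_len")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction out of (0, 1]")


# -- VCF input ----------------------------------------------------------------


def _info_int(variant, fmt_reader, key: str) -> int:
    val = variant.INFO.get(key)
    if val is None:
        arr = fmt_reader(key)
        if arr is not None and arr.size:
            val = arr.flat[0]
    if val is None:
        return 0
    return int(val)


def parse_sv_vcf(path: str | Path, sample_id: str, group: str) -> list[SVCall]:
    """Read one sample's SV VCF into :class:`SVCall` records.

    DEL/DUP/INV records lacking an INFO END are rejected individually (with
    a log message), not fatally.  A VCF without an SVTYPE INFO definition is
    a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SV VCF not found: {path}")
    vcf = VCF(str(path))
    info_keys = {
        h["ID"] for h in vcf.header_iter() if h["HeaderType"] == "INFO"
    }
    if "SVTYPE" not in info_keys:
        raise ValueError(f"{path}: no SVTYPE INFO field in header; not an SV VCF")

    def fmt_reader(key):
        try:
            return vcf_variant.format(key)
        except KeyError:
            return None

    calls: list[SVCall] = []
    for vcf_variant in vcf:
        svtype = vcf_variant.INFO.get("SVTYPE")
        if svtype is None or svtype not in SVTYPES:
            logger.warning("%s: record %s has no usable SVTYPE; skipped",
                           path, vcf_variant.ID)
            continue
        start = vcf_variant.start  # 0-based
        pe = _info_int(vcf_variant, fmt_reader, "PE")
        sr = _info_int(vcf_variant, fmt_reader, "SR")
        if svtype == "BND":
            calls.append(
                SVCall(sample_id, group, "BND", vcf_variant.CHROM, start,
                       start + 1, pe, sr, vcf_variant.ID,
                       vcf_variant.INFO.get("MATEID"))
            )
            continue
        raw_end = vcf_variant.INFO.get("END")
        if raw_end is None:
            logger.warning("%s: %s record %s lacks INFO END; rejected",
                           path, svtype, vcf_variant.ID)
            continue
        calls.append(
            SVCall(sample_id, group, svtype, vcf_variant.CHROM, start,
                   int(raw_end), pe, sr, vcf_variant.ID)
        )
    return calls


# -- Filters ------------------------------------------------------------------


def filter_by_length(
    calls: Iterable[SVCall], policy: FilterPolicy = FilterPolicy()
) -> list[SVCall]:
    """Keep DEL/DUP with min_len <= length <= max_len; pass INV/BND through."""
    out = []
    for c in calls:
        if c.svtype in CNV_TYPES and not (policy.min_len <= c.length <= policy.max_len):
            continue
        out.append(c)
    return out


def passes_support(call: SVCall, coverage: float,
                   policy: FilterPolicy = FilterPolicy()) -> bool:
    primary = policy.coverage_fraction * coverage
    pe, sr = call.pe_support, call.sr_support
    return (pe > primary and sr > policy.secondary_sr_min) or (
        sr > primary and pe > policy.secondary_pe_min
    )


def filter_by_support(
    calls: Iterable[SVCall],
    coverage: Mapping[str, float],
    policy: FilterPolicy = FilterPolicy(),
) -> list[SVCall]:
    """Keep calls meeting the primary/secondary support rule at the sample's coverage."""
    calls = list(calls)
    missing = sorted({c.sample_id for c in calls} - set(coverage))
    if missing:
        raise KeyError(f"no genome coverage known for sample(s): {missing}")
    return [c for c in calls if passes_support(c, coverage[c.sample_id], policy)]


# -- Group tallies ------------------------------------------------------------


def tally_by_group(
    calls: Sequence[SVCall],
    genome: GenomeDef,
    denominator: GenomeDef | None = None,
) -> pd.DataFrame:
    """Per-group counts, summed lengths (kb) and genome-covered fractions.

    Covered fractions use the *merged footprint* of the group's calls of each
    type (union, not sum of lengths) over the ``denominator`` genome
    (default: the full ``genome``; pass an autosome subset to reproduce
    autosome-based coverage figures).
    """
    denom = denominator if denominator is not None else genome
    denom_bp = denom.total_length
    groups = sorted({c.group for c in calls})
    rows = []
    for label, subset in [(g, [c for c in calls if c.group == g]) for g in groups] + [
        ("Total", list(calls))
    ]:
        row: dict[str, object] = {"group": label}
        for t in SVTYPES:
            row[f"count_{t}"] = sum(c.svtype == t for c in subset)
        row["count_total"] = len(subset)
        total_kb = 0.0
        for t in _INTERVAL_TYPES:
            kb = sum(c.length for c in subset if c.svtype == t) / 1000.0
            row[f"length_kb_{t}"] = round(kb, 2)
            total_kb += kb
        row["length_kb_total"] = round(total_kb, 2)
        interval_calls = [
            c for c in subset if c.svtype in _INTERVAL_TYPES and c.chrom in denom
        ]
        for t in _INTERVAL_TYPES:
            bp = covered_bp([c for c in interval_calls if c.svtype == t])
            row[f"covered_pct_{t}"] = round(100.0 * bp / denom_bp, 3)
        row["covered_pct_total"] = round(
            100.0 * covered_bp(interval_calls) / denom_bp, 3
        )
        rows.append(row)
    return pd.DataFrame(rows)


# -- Coverage table and VCF output --------------------------------------------


def read_coverage_table(path: str | Path) -> dict[str, float]:
    """Read a sample<TAB>fold coverage table."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, fold = line.split("\t")[:2]
            out[sample] = float(fold)
    return out


def write_coverage_table(coverage: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, fold in coverage.items():
            fh.write(f"{sample}\t{fold}\n")


_VCF_HEADER_INFO = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Difference in length between REF and ALT alleles">
##INFO=<ID=PE,Number=1,Type=Integer,Description="Number of paired-end reads supporting the variant">
##INFO=<ID=SR,Number=1,Type=Integer,Description="Number of split reads supporting the variant">
##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">
"""


def write_sv_vcf(calls: Sequence[SVCall], genome: GenomeDef, path: str | Path) -> None:
    """Write calls as a VCF v4.2 with SVTYPE/END/SVLEN/PE/SR INFO keys."""
    order = {name: i for i, name in enumerate(genome.names)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(_VCF_HEADER_INFO)
        for name, length in genome:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (order.get(c.chrom, 1 << 30), c.start)):
            pos = c.start + 1  # back to 1-based
            cid = c.call_id or "."
            if c.svtype == "BND":
                alt = f"N[{c.chrom}:{pos + 1}["
                info = f"SVTYPE=BND;PE={c.pe_support};SR={c.sr_support}"
                if c.mate_id:
                    info += f";MATEID={c.mate_id}"
            else:
                alt = f"<{c.svtype}>"
                svlen = c.length if c.svtype != "DEL" else -c.length
                info = (
                    f"SVTYPE={c.svtype};END={c.end};SVLEN={svlen};"
                    f"PE={c.pe_support};SR={c.sr_support}"
                )
            fh.write(f"{c.chrom}\t{pos}\t{cid}\tN\t{alt}\t.\t.\t{info}\n")


def relabel(calls: Iterable[SVCall], sample_id: str | None = None,
            group: str | None = None) -> list[SVCall]:
    """Return copies with sample/group labels replaced where given."""
    out = []
    for c in calls:
        out.append(replace(c, sample_id=sample_id or c.sample_id,
                           group=group or c.group))
    return out
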
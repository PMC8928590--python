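"""SV VCF parsing, length/support filters, group tallies."""

import numpy as np
import pytest

from spermcnv.genome import GenomeDef
from spermcnv.variants import (
    FilterPolicy,
    SVCall,
    filter_by_length,
    filter_by_support,
    parse_sv_vcf,
    passes_support,
    tally_by_group,
    write_sv_vcf,
)

GENOME = GenomeDef.from_dict({"chr1": 10_000_000, "chr2": 10_000_000})

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=END,Number=1,Type=Integer,Description="e">
##INFO=<ID=PE,Number=1,Type=Integer,Description="p">
##INFO=<ID=SR,Number=1,Type=Integer,Description="s">
##contig=<ID=chr1,length=10000000>
##contig=<ID=chr2,length=10000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def make_call(svtype="DEL", start=1000, end=2000, pe=5, sr=3, sample="s1",
              group="g1", chrom="chr1"):
    return SVCall(sample, group, svtype, chrom, start, end, pe, sr)


class TestParse:
    def test_header_only_vcf_yields_empty_set(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(VCF_HEADER)
        assert parse_sv_vcf(p, "s1", "g1") == []

    def test_one_based_coordinates_become_half_open(self, tmp_path):
        p = tmp_path / "one.vcf"
        p.write_text(VCF_HEADER +
                     "chr1\t101\tev1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=200;PE=5;SR=3\n")
        (call,) = parse_sv_vcf(p, "s1", "g1")
        assert (call.start, call.end, call.length) == (100, 200, 100)

    def test_per_type_counts_match_line_count_oracle(self, tmp_path):
        rng = np.random.default_rng(4)
        lines = []
        for i in range(20):
            t = ["DEL", "DUP", "INV", "BND"][int(rng.integers(0, 4))]
            pos = int(rng.integers(1000, 9000))
            if t == "BND":
                lines.append(f"chr1\t{pos}\tb{i}\tN\tN[chr2:500[\t.\t.\tSVTYPE=BND;PE=4;SR=2")
            else:
                lines.append(f"chr1\t{pos}\tv{i}\tN\t<{t}>\t.\t.\tSVTYPE={t};END={pos+499};PE=4;SR=2")
        p = tmp_path / "mixed.vcf"
        text = VCF_HEADER + "\n".join(lines) + "\n"
        p.write_text(text)
        calls = parse_sv_vcf(p, "s1", "g1")
        for t in ("DEL", "DUP", "INV", "BND"):
            expected = sum(f"SVTYPE={t}" in ln for ln in text.splitlines())
            assert sum(c.svtype == t for c in calls) == expected

    def test_interval_record_without_end_rejected_not_fatal(self, tmp_path, caplog):
        p = tmp_path / "noend.vcf"
        p.write_text(VCF_HEADER +
                     "chr1\t101\tev1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;PE=5;SR=3\n"
                     "chr1\t501\tev2\tN\t<DUP>\t.\t.\tSVTYPE=DUP;END=600;PE=5;SR=3\n")
        calls = parse_sv_vcf(p, "s1", "g1")
        assert [c.svtype for c in calls] == ["DUP"]

    def test_missing_svtype_header_is_fatal_with_path(self, tmp_path):
        p = tmp_path / "nosvtype.vcf"
        p.write_text("##fileformat=VCFv4.2\n"
                     '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
                     "##contig=<ID=chr1,length=1000>\n"
                     "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        with pytest.raises(ValueError, match="nosvtype.vcf"):
            parse_sv_vcf(p, "s1", "g1")

    def test_unreadable_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_sv_vcf(tmp_path / "absent.vcf", "s1", "g1")

    def test_round_trip_through_writer(self, tmp_path):
        calls = [make_call("DEL", 100, 200), make_call("DUP", 500, 9_000),
                 make_call("INV", 1_000, 3_000), make_call("BND", 4_000, 4_001)]
        p = tmp_path / "rt.vcf"
        write_sv_vcf(calls, GENOME, p)
        back = parse_sv_vcf(p, "s1", "g1")
        assert [(c.svtype, c.start, c.end, c.pe_support, c.sr_support) for c in calls] == \
               [(c.svtype, c.start, c.end, c.pe_support, c.sr_support) for c in back]


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(49, False), (50, True),
                                             (5_000_000, True), (5_000_001, False)])
    def test_bounds_inclusive_at_50bp_and_5mb(self, length, kept):
        call = make_call("DEL", 0, length)
        assert (filter_by_length([call]) == [call]) is kept

    def test_inv_and_bnd_pass_through_unchanged(self):
        calls = [make_call("INV", 0, 10), make_call("BND", 5, 6)]
        assert filter_by_length(calls) == calls

    def test_matches_per_record_recheck_oracle(self):
        rng = np.random.default_rng(8)
        calls = []
        for _ in range(500):
            t = ["DEL", "DUP", "INV"][int(rng.integers(0, 3))]
            length = int(10 ** rng.uniform(0, 7))
            calls.append(make_call(t, 0, max(1, length)))
        kept = filter_by_length(calls)
        expected = [c for c in calls
                    if c.svtype not in ("DEL", "DUP") or 50 <= c.length <= 5_000_000]
        assert kept == expected


class TestSupportFilter:
    def test_pe_primary_with_secondary_sr(self):
        assert passes_support(make_call(pe=4, sr=2), coverage=4.0)

    def test_secondary_sr_condition_failing_removes_call(self):
        assert not passes_support(make_call(pe=4, sr=1), coverage=4.0)

    def test_sr_primary_with_secondary_pe(self):
        assert passes_support(make_call(pe=4, sr=4), coverage=4.0)
        assert not passes_support(make_call(pe=3, sr=4), coverage=4.0)

    def test_threshold_is_real_valued_and_strict(self):
        # 0.75 * 6 = 4.5: PE=5 passes, PE=4 does not
        assert passes_support(make_call(pe=5, sr=2), coverage=6.0)
        assert not passes_support(make_call(pe=4, sr=2), coverage=6.0)

    def test_unknown_coverage_is_fatal_and_names_sample(self):
        with pytest.raises(KeyError, match="s1"):
            filter_by_support([make_call()], {"other": 4.0})

    def test_filters_are_idempotent_and_commute(self):
        rng = np.random.default_rng(12)
        calls = [make_call("DEL", 0, int(10 ** rng.uniform(1, 7)),
                           pe=int(rng.integers(0, 8)), sr=int(rng.integers(0, 8)))
                 for _ in range(300)]
        cov = {"s1": 4.0}
        a = filter_by_support(filter_by_length(calls), cov)
        assert filter_by_support(filter_by_length(a), cov) == a
        b = filter_by_length(filter_by_support(calls, cov))
        assert a == b
        assert all(c in calls for c in a)


class TestTally:
    def test_empty_input_is_all_zero(self):
        df = tally_by_group([], GENOME)
        assert df.count_total.tolist() == [0]

    def test_union_vs_sum_distinction(self):
        calls = [make_call("DEL", 1000, 2000, sample="a"),
                 make_call("DEL", 1000, 2000, sample="b")]
        row = tally_by_group(calls, GENOME).iloc[0]
        assert row.length_kb_DEL == 2.0
        covered = row.covered_pct_DEL / 100 * GENOME.total_length
        assert covered == pytest.approx(1000)

    def test_matches_per_record_accumulation_oracle(self):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(50):
            t = ["DEL", "DUP", "INV", "BND"][int(rng.integers(0, 4))]
            s = int(rng.integers(0, 1_000_000))
            e = s + (1 if t == "BND" else int(rng.integers(100, 10_000)))
            calls.append(make_call(t, s, e, group=f"g{i % 2}"))
        df = tally_by_group(calls, GENOME).set_index("group")
        for grp in ("g0", "g1"):
            sub = [c for c in calls if c.group == grp]
            for t in ("DEL", "DUP", "INV", "BND"):
                assert df.loc[grp, f"count_{t}"] == sum(c.svtype == t for c in sub)
            assert df.loc[grp, "length_kb_DEL"] == pytest.approx(
                sum(c.length for c in sub if c.svtype == "DEL") / 1000, abs=0.005
            )
        assert df.loc["Total", "count_total"] == len(calls)
        assert (df.loc[["g0", "g1"], "count_total"].sum()
                == df.loc["Total", "count_total"])


def test_policy_validation():
    with pytest.raises(ValueError):
        FilterPolicy(min_len=100, max_len=100)
    with pytest.raises(ValueError):
        FilterPolicy(coverage_fraction=1.5)
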
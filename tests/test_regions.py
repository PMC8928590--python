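"""Interval algebra: merge, subtract, flanks, per-chromosome summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermcnv.genome import GenomeDef
from spermcnv.regions import (
    Region,
    covered_bp,
    flank_regions,
    intersect_regions,
    merge_regions,
    per_chromosome_summary,
    subtract_regions,
)

from conftest import random_regions
from oracles import brute_covered_bp, brute_flanks, brute_merge, brute_subtract


def regs(*triples):
    return [Region(c, s, e) for c, s, e in triples]


def triples(regions):
    return [(r.chrom, r.start, r.end) for r in regions]


class TestMerge:
    def test_book_ended_intervals_merge_at_gap_zero(self):
        out = merge_regions(regs(("c", 10, 20), ("c", 20, 30)))
        assert triples(out) == [("c", 10, 30)]

    def test_gap_parameter_bridges_separation(self):
        r = regs(("c", 10, 20), ("c", 25, 30))
        assert len(merge_regions(r, gap=0)) == 2
        assert triples(merge_regions(r, gap=5)) == [("c", 10, 30)]

    def test_merge_is_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(0)
        g = GenomeDef.from_dict({"c1": 100_000, "c2": 100_000})
        r = random_regions(rng, g, 100, max_len=5_000)
        once = merge_regions(r)
        assert merge_regions(once) == once
        shuffled = [r[i] for i in rng.permutation(len(r))]
        assert merge_regions(shuffled) == once

    def test_union_measure_preserved_at_gap_zero(self):
        rng = np.random.default_rng(1)
        g = GenomeDef.from_dict({"c1": 5_000})
        r = random_regions(rng, g, 50, max_len=300)
        assert covered_bp(merge_regions(r)) == covered_bp(r) == brute_covered_bp(triples(r))

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("gap", [0, 7])
    def test_matches_pairwise_absorption_oracle(self, seed, gap):
        rng = np.random.default_rng(seed)
        g = GenomeDef.from_dict({"c1": 10_000, "c2": 10_000})
        r = random_regions(rng, g, 200, max_len=200)
        assert triples(merge_regions(r, gap=gap)) == brute_merge(triples(r), gap)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_regions([], gap=-1)


class TestSubtractIntersect:
    def test_subtract_matches_positionwise_oracle(self):
        rng = np.random.default_rng(3)
        g = GenomeDef.from_dict({"c1": 4_000})
        a = random_regions(rng, g, 40, max_len=200)
        b = random_regions(rng, g, 40, max_len=200)
        assert triples(subtract_regions(a, b)) == brute_subtract(triples(a), triples(b))

    def test_intersection_of_disjoint_sets_is_empty(self):
        assert intersect_regions(regs(("c", 0, 10)), regs(("c", 10, 20))) == []

    def test_intersection_bp_identity(self):
        a = regs(("c", 0, 100), ("c", 150, 200))
        b = regs(("c", 50, 160))
        assert covered_bp(intersect_regions(a, b)) == 60


class TestFlanks:
    def test_flank_clipped_at_chromosome_start(self):
        g = GenomeDef.from_dict({"c": 10_000})
        out = flank_regions(regs(("c", 0, 100)), 5_000, g)
        assert triples(out) == [("c", 100, 5_100)]

    def test_flanks_never_cover_input_regions(self):
        g = GenomeDef.from_dict({"c": 100_000})
        inputs = regs(("c", 10_000, 11_000), ("c", 12_000, 13_000))
        flanks = flank_regions(inputs, 5_000, g)
        assert covered_bp(intersect_regions(flanks, inputs)) == 0
        # the inter-region gap is fully flanked but truncated at the regions
        assert ("c", 11_000, 12_000) in triples(flanks)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_construct_then_subtract_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = GenomeDef.from_dict({"c1": 50_000, "c2": 30_000})
        r = random_regions(rng, g, 60, max_len=2_000)
        got = triples(flank_regions(r, 1_500, g))
        lengths = {c: g.length_of(c) for c in g.names}
        assert got == brute_flanks(triples(r), 1_500, lengths)

    def test_nonpositive_size_rejected(self):
        g = GenomeDef.from_dict({"c": 1_000})
        with pytest.raises(ValueError):
            flank_regions([], 0, g)


class TestPerChromosomeSummary:
    def test_empty_input_gives_zero_rows_for_all_chromosomes(self):
        g = GenomeDef.from_dict({"c1": 1_000, "c2": 2_000})
        df = per_chromosome_summary([], g)
        assert list(df.chrom) == ["c1", "c2"]
        assert df.covered_bp.tolist() == [0, 0]

    def test_full_chromosome_is_100_percent(self):
        g = GenomeDef.from_dict({"c1": 1_000_000})
        df = per_chromosome_summary(regs(("c1", 0, 1_000_000)), g)
        assert df.pct_covered.tolist() == [100.0]

    def test_matches_accumulation_oracle(self):
        rng = np.random.default_rng(9)
        g = GenomeDef.from_dict({"c1": 8_000, "c2": 8_000})
        r = random_regions(rng, g, 80, max_len=400)
        df = per_chromosome_summary(r, g).set_index("chrom")
        for chrom in g.names:
            mine = [t for t in triples(r) if t[0] == chrom]
            assert df.loc[chrom, "covered_bp"] == brute_covered_bp(mine)
            assert df.loc[chrom, "n_regions"] == len(mine)

    def test_unknown_chromosome_is_fatal(self):
        g = GenomeDef.from_dict({"c1": 1_000})
        with pytest.raises(KeyError, match="cX"):
            per_chromosome_summary(regs(("cX", 0, 10)), g)


@st.composite
def interval_lists(draw):
    n = draw(st.integers(1, 40))
    out = []
    for _ in range(n):
        s = draw(st.integers(0, 500))
        out.append(Region(draw(st.sampled_from(["cA", "cB"])),
                          s, s + draw(st.integers(1, 80))))
    return out


@settings(max_examples=200, deadline=None, derandomize=True)
@given(interval_lists(), st.integers(0, 10))
def test_merge_properties_hold_for_arbitrary_inputs(regions, gap):
    """Merged output is sorted, disjoint beyond gap, covers the input."""
    merged = merge_regions(regions, gap=gap)
    by_chrom = {}
    for r in merged:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom_regions in by_chrom.values():
        for a, b in zip(chrom_regions, chrom_regions[1:]):
            assert b.start > a.end + gap
    assert covered_bp(merged) >= covered_bp(regions)
    if gap == 0:
        assert covered_bp(merged) == covered_bp(regions)
    # every input interval is contained in some merged interval
    for r in regions:
        assert any(m.chrom == r.chrom and m.start <= r.start and r.end <= m.end
                   for m in merged)


def test_region_validation_rejects_inverted_intervals():
    with pytest.raises(ValueError):
        Region("c", 10, 10)
    with pytest.raises(ValueError):
        Region("c", -1, 5)
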
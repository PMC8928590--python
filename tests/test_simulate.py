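"""The synthetic-data generator: determinism, planted structure, truth tables."""

import numpy as np
import pytest

from spermcnv._rng import substream
from spermcnv.simulate import (
    DEMO_SHARING_PROFILE,
    GROUP_S1,
    SimulationConfig,
    generate_callsets,
    generate_genome,
    generate_repeats,
    generate_segdup_pairs,
    write_simulation,
)
from spermcnv.variants import FilterPolicy, passes_support


def small_cfg(**kw):
    defaults = dict(
        n_chromosomes=4,
        chrom_length_range=(20_000_000, 30_000_000),
        sharing_profile={},
        cnv_counts_per_sample=10,
        inv_per_sample=2,
        bnd_per_sample=4,
        event_length_range=(50, 50_000),
        repeat_class_densities={"Satellite": 0.02},
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_degenerate_range_gives_exact_length(self):
        cfg = SimulationConfig(n_chromosomes=1,
                               chrom_length_range=(1_000_000, 1_000_000))
        g = generate_genome(cfg)
        assert g.chromosomes == (("chr1", 1_000_000),)

    def test_same_seed_reproduces_genome(self):
        cfg = SimulationConfig(seed=7)
        assert generate_genome(cfg) == generate_genome(cfg)

    def test_lengths_in_range_and_total_matches_redraw_oracle(self):
        cfg = SimulationConfig(n_chromosomes=29,
                               chrom_length_range=(40_000_000, 160_000_000),
                               seed=7)
        g = generate_genome(cfg)
        assert len(g) == 29
        assert all(40_000_000 <= l <= 160_000_000 for _, l in g)
        redraw = substream(7, "genome").integers(40_000_000, 160_000_001, size=29)
        assert g.total_length == int(redraw.sum())

    def test_inverted_range_rejected_with_message(self):
        with pytest.raises(ValueError, match="chrom_length_range"):
            SimulationConfig(chrom_length_range=(100, 50))


class TestRepeats:
    def test_zero_densities_give_empty_annotation(self):
        cfg = small_cfg(repeat_class_densities={})
        g = generate_genome(cfg)
        assert generate_repeats(g, cfg) == []

    def test_satellite_density_realized_within_10_percent(self):
        cfg = small_cfg(repeat_class_densities={"Satellite": 0.05},
                        n_chromosomes=5,
                        chrom_length_range=(10_000_000, 10_000_000))
        g = generate_genome(cfg)
        feats = generate_repeats(g, cfg)
        frac = sum(f.length for f in feats) / g.total_length
        assert 0.045 <= frac <= 0.055

    def test_within_class_features_do_not_overlap(self):
        cfg = small_cfg(repeat_class_densities={"LINE": 0.3, "SINE": 0.1})
        g = generate_genome(cfg)
        feats = generate_repeats(g, cfg)
        for cls in ("LINE", "SINE"):
            per = sorted((f.chrom, f.start, f.end) for f in feats
                         if f.repeat_class == cls)
            for (c1, s1, e1), (c2, s2, _) in zip(per, per[1:]):
                assert c1 != c2 or s2 >= e1

    def test_fixed_seed_gives_byte_identical_table(self, tmp_path):
        cfg = small_cfg()
        g = generate_genome(cfg)
        from spermcnv.repeats import write_repeat_table

        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_repeat_table(generate_repeats(g, cfg), p1)
        write_repeat_table(generate_repeats(g, cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_density_sum_above_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            small_cfg(repeat_class_densities={"LINE": 0.7, "SINE": 0.4})


class TestSegDups:
    def test_zero_count_gives_empty_set(self):
        cfg = small_cfg(segdup_pair_count=0)
        g = generate_genome(cfg)
        assert generate_segdup_pairs(g, cfg) == []

    def test_zero_sd_gives_exact_identity(self):
        cfg = small_cfg(segdup_pair_count=50, segdup_identity_mean=0.9,
                        segdup_identity_sd=0.0)
        g = generate_genome(cfg)
        assert {p.identity for p in generate_segdup_pairs(g, cfg)} == {0.9}

    def test_interchromosomal_fraction_matches_recount(self):
        cfg = small_cfg(segdup_pair_count=1000, segdup_interchrom_prob=0.6)
        g = generate_genome(cfg)
        pairs = generate_segdup_pairs(g, cfg)
        recount = sum(p.fragment_a.chrom != p.fragment_b.chrom for p in pairs)
        assert sum(p.interchromosomal for p in pairs) == recount
        assert recount / len(pairs) == pytest.approx(0.6, abs=0.05)


class TestCallsets:
    def test_demo_profile_plants_433_events_with_exact_category_counts(self):
        cfg = SimulationConfig(cnv_counts_per_sample=0, inv_per_sample=0,
                               bnd_per_sample=0, repeat_class_densities={},
                               distal_bias=0.0, satellite_colocation_prob=0.0,
                               seed=3)
        g = generate_genome(cfg)
        sim = generate_callsets(g, [], cfg)
        truth = sim.events[~sim.events.is_singleton]
        assert len(truth) == 433
        assert truth.venn_category.value_counts().to_dict() == DEMO_SHARING_PROFILE

    def test_every_vcf_record_maps_to_exactly_one_truth_row(self):
        cfg = small_cfg(sharing_profile={GROUP_S1: 5})
        g = generate_genome(cfg)
        reps = generate_repeats(g, cfg)
        sim = generate_callsets(g, reps, cfg)
        vcf_ids = [c.call_id for c in sim.all_calls()]
        assert sorted(vcf_ids) == sorted(sim.calls.call_id)
        assert sim.calls.call_id.is_unique
        assert set(sim.calls.event_id) == set(sim.events.event_id)

    def test_distal_bias_zero_gives_uniform_terminal_fraction(self):
        cfg = small_cfg(cnv_counts_per_sample=100, inv_per_sample=0,
                        bnd_per_sample=0, distal_bias=0.0,
                        satellite_colocation_prob=0.0,
                        repeat_class_densities={}, seed=5)
        g = generate_genome(cfg)
        sim = generate_callsets(g, [], cfg)
        ev = sim.events
        mids = (ev.start + ev.end) / 2
        lengths = ev.chrom.map(dict(g.chromosomes))
        frac = mids / lengths
        terminal10 = ((frac < 0.10) | (frac >= 0.90)).mean()
        n = len(ev)
        # binomial sd at p=0.2 over ~1700 events
        assert terminal10 == pytest.approx(0.20, abs=4 * np.sqrt(0.2 * 0.8 / n))

    def test_distal_bias_one_with_zero_window_stays_in_terminal_5pct(self):
        cfg = small_cfg(cnv_counts_per_sample=30, inv_per_sample=0,
                        bnd_per_sample=0, distal_bias=1.0, distal_window_bp=0,
                        event_length_range=(50, 10_000),
                        repeat_class_densities={}, seed=6)
        g = generate_genome(cfg)
        sim = generate_callsets(g, [], cfg)
        ev = sim.events
        frac = ((ev.start + ev.end) / 2) / ev.chrom.map(dict(g.chromosomes))
        assert bool(((frac < 0.05) | (frac >= 0.95)).all())
        assert bool(ev.placed_distal.all())

    def test_satellite_colocation_prob_one_places_midpoints_in_satellites(self):
        cfg = small_cfg(satellite_colocation_prob=1.0, distal_bias=0.0,
                        cnv_counts_per_sample=20, inv_per_sample=0,
                        bnd_per_sample=0, event_length_range=(50, 5_000), seed=7)
        g = generate_genome(cfg)
        reps = generate_repeats(g, cfg)
        sim = generate_callsets(g, reps, cfg)
        sats = [(f.chrom, f.start, f.end) for f in reps]
        assert bool(sim.events.placed_in_satellite.all())
        for _, ev in sim.events.iterrows():
            mid = (ev.start + ev.end) / 2
            assert any(c == ev.chrom and s <= mid < e for c, s, e in sats)

    def test_support_pass_rate_matches_configuration_within_3pct(self):
        cfg = small_cfg(n_chromosomes=8, cnv_counts_per_sample=60,
                        inv_per_sample=0, bnd_per_sample=0,
                        support_pass_fraction=0.7, seed=8)
        g = generate_genome(cfg)
        sim = generate_callsets(g, [], cfg)
        calls = sim.calls
        assert len(calls) >= 1000
        rate = calls.passes_support.mean()
        assert rate == pytest.approx(0.7, abs=0.03)
        # pass flags agree with the filter itself
        for c in sim.all_calls():
            row = calls[calls.call_id == c.call_id].iloc[0]
            assert passes_support(c, sim.coverage[c.sample_id]) == row.passes_support

    def test_impossible_event_placement_is_explicit_failure(self):
        cfg = small_cfg(n_chromosomes=1,
                        chrom_length_range=(100_000, 100_000),
                        event_length_range=(200_000, 200_000),
                        cnv_counts_per_sample=1)
        g = generate_genome(cfg)
        with pytest.raises(RuntimeError):
            generate_callsets(g, [], cfg)

    def test_write_simulation_is_deterministic(self, tmp_path):
        cfg = small_cfg(cnv_counts_per_sample=5)
        g = generate_genome(cfg)
        reps = generate_repeats(g, cfg)
        sd = generate_segdup_pairs(g, cfg)
        outs = []
        for d in ("a", "b"):
            sim = generate_callsets(g, reps, cfg)
            paths = write_simulation(tmp_path / d, cfg, g, reps, sd, sim)
            outs.append(paths)
        for key in outs[0]:
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes()


def test_yaml_round_trip(tmp_path):
    cfg = small_cfg(distal_bias=0.4)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    assert SimulationConfig.from_yaml(p) == cfg


def test_unknown_yaml_key_rejected(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("n_chromosomes: 3\nbogus_knob: 5\n")
    with pytest.raises(ValueError, match="bogus_knob"):
        SimulationConfig.from_yaml(p)
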
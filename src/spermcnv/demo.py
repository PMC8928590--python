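"""Worked-example inputs: published summary tallies as synthetic tables.

The study-scale headline inputs (counts from the published SegDup and CNV
sharing analyses of the cattle single-sperm data set) are represented here
as *composition targets*: synthetic tables are constructed to match the
published raw counts exactly, and every percentage is then recomputed by
the package's own summarizers.  Nothing here stores a percentage.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .genome import GenomeDef
from .regions import Region
from .segdup import SegDupPair
from .sharing import cluster_events, remove_singletons, venn_summary
from .simulate import (
    DEMO_SHARING_PROFILE,
    SimulationConfig,
    generate_callsets,
    generate_genome,
)
from .variants import filter_by_length, filter_by_support

__all__ = [
    "SEGDUP_PAIR_COUNTS",
    "segdup_pairs_matching_counts",
    "demo_sharing_venn",
]

# Raw tallies of the published pairwise SegDup table (counts, not
# percentages): total pairs, pairs with identity > 80% / > 90%, pairs in
# reversed orientation, and interchromosomal pairs.
SEGDUP_PAIR_COUNTS = {
    "n_pairs": 27_560,
    "identity_gt_80": 12_400,
    "identity_gt_90": 3_374,
    "reversed": 17_477,
    "interchromosomal": 16_621,
}


def segdup_pairs_matching_counts(
    counts: dict[str, int] | None = None, seed: int = 0
) -> list[SegDupPair]:
    """Build a synthetic pair table whose composition equals ``counts``.

    Identities are drawn uniformly within the (<=80%, 80-90%, >90%] bands,
    orientation and chromosomal-distribution flags are assigned to the first
    ``reversed`` / ``interchromosomal`` pairs, and the table is shuffled.
    """
    c = dict(SEGDUP_PAIR_COUNTS if counts is None else counts)
    n = c["n_pairs"]
    rng = substream(seed, "demo-segdup")
    genome = GenomeDef.from_dict({f"chr{i}": 10_000_000 for i in range(1, 11)})
    names = genome.names

    n_hi = c["identity_gt_90"]
    n_mid = c["identity_gt_80"] - n_hi
    n_lo = n - c["identity_gt_80"]
    identities = np.concatenate([
        rng.uniform(0.50, 0.80, n_lo),
        rng.uniform(0.8000001, 0.90, n_mid),
        rng.uniform(0.9000001, 1.00, n_hi),
    ])
    reversed_flags = np.arange(n) < c["reversed"]
    inter_flags = np.arange(n) < c["interchromosomal"]
    for key, arr in (("ident", identities), ("rev", reversed_flags),
                     ("inter", inter_flags)):
        substream(seed, "demo-segdup-shuffle", key).shuffle(arr)

    pairs = []
    for i in range(n):
        ia = int(rng.integers(0, len(names)))
        if inter_flags[i]:
            ib = int((ia + 1 + rng.integers(0, len(names) - 1)) % len(names))
        else:
            ib = ia
        frag_len = int(rng.integers(500, 5_000))
        fr = []
        for ci in (ia, ib):
            s = int(rng.integers(0, genome.length_of(names[ci]) - frag_len))
            fr.append(Region(names[ci], s, s + frag_len))
        pairs.append(
            SegDupPair(fr[0], fr[1], float(identities[i]),
                       same_orientation=not bool(reversed_flags[i]))
        )
    return pairs


def demo_sharing_venn(seed: int = 0):
    """Run the sharing worked example end to end and return its Venn table.

    Plants the demo profile (433 non-singleton DEL/DUP events over the two
    sperm groups and the trio), applies the length and support filters, and
    flows the surviving calls through cluster -> singleton removal -> Venn
    summary.
    """
    cfg = SimulationConfig(
        sharing_profile=dict(DEMO_SHARING_PROFILE),
        cnv_counts_per_sample=20,
        repeat_class_densities={},
        satellite_colocation_prob=0.0,
        seed=seed,
    )
    genome = generate_genome(cfg)
    sim = generate_callsets(genome, [], cfg)
    kept = filter_by_support(filter_by_length(sim.all_calls()), sim.coverage)
    clusters = remove_singletons(cluster_events(kept))
    return venn_summary(clusters)
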
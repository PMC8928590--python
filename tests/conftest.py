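import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from spermcnv.genome import GenomeDef
from spermcnv.regions import Region
from spermcnv.simulate import SimulationConfig, generate_genome, generate_repeats


@pytest.fixture(scope="session")
def toy_genome() -> GenomeDef:
    """Five 10 Mb chromosomes (50 Mb toy genome)."""
    return GenomeDef.from_dict({f"chr{i}": 10_000_000 for i in range(1, 6)})


@pytest.fixture(scope="session")
def toy_repeats(toy_genome):
    cfg = SimulationConfig(
        n_chromosomes=5,
        chrom_length_range=(10_000_000, 10_000_000),
        repeat_class_densities={"LINE": 0.2, "SINE": 0.1, "Satellite": 0.02},
        seed=11,
    )
    return generate_repeats(toy_genome, cfg)


def random_regions(rng: np.random.Generator, genome: GenomeDef, n: int,
                   max_len: int = 200_000) -> list[Region]:
    names = genome.names
    out = []
    for _ in range(n):
        chrom = names[rng.integers(0, len(names))]
        L = genome.length_of(chrom)
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, L - length))
        out.append(Region(chrom, start, start + length))
    return out
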
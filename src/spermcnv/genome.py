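"""Genome definition: an ordered set of chromosomes with lengths.

The :class:`GenomeDef` fixes the coordinate space for every interval
operation in the package and supplies the denominators for "fraction of
genome covered" style statistics.  All coordinates elsewhere are 0-based
half-open; chromosome lengths are in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

__all__ = ["GenomeDef"]


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names and lengths."""

    chromosomes: tuple[tuple[str, int], ...]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome definition")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "GenomeDef":
        return cls(tuple((str(k), int(v)) for k, v in lengths.items()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome definition") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def subset(self, names: Sequence[str]) -> "GenomeDef":
        keep = set(names)
        return GenomeDef(tuple((c, l) for c, l in self.chromosomes if c in keep))

    # -- chrom.sizes dialect (name<TAB>length) --------------------------------

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")

    @classmethod
    def read_chrom_sizes(cls, path: str | Path) -> "GenomeDef":
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split("\t")[:2]
                chroms.append((name, int(length)))
        return cls(tuple(chroms))
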
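"""Seed-stable random streams.

Every stochastic routine in the package draws from a ``numpy`` Generator
obtained through :func:`substream`, which derives an independent stream from
a master seed plus a tuple of string/int keys.  Keys are hashed with CRC32 so
that adding a new stream (e.g. one more sample) never shifts the draws of an
existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the (seed, \\*keys) stream.

    The same (seed, keys) pair always yields an identical stream; distinct
    key tuples yield statistically independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
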
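"""Deterministic per-operation random streams.

All stochastic operations derive an independent numpy Generator from one
user-facing integer seed plus a tuple of string/int tags naming the
operation (and, e.g., the library label).  Identical seeds and tags give
identical streams on every platform.
"""

from __future__ import annotations

import zlib

import numpy as np


def spawn_rng(seed: int, *tags: object) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a tag path.

    Tags are hashed with crc32 so that any mix of strings and small ints
    can be used; the entropy pool is a SeedSequence over the combined
    words, so streams for different tag paths are statistically
    independent.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        words.append(zlib.crc32(repr(t).encode("utf8")) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))
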
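"""Named, reproducible RNG substreams.

A master seed plus a tuple of string/int keys maps deterministically to a
``SeedSequence``, so every stage (per species, per restart, per fold, per
permutation) draws from its own stream and stages can be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_seed(master: int, *keys) -> np.random.SeedSequence:
    """Deterministic child seed for ``(master, *keys)``."""
    entropy = [int(master) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def rng_for(master: int, *keys) -> np.random.Generator:
    """A ``Generator`` seeded from the named substream."""
    return np.random.default_rng(child_seed(master, *keys))
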
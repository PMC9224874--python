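"""Seeding helpers.

Every stochastic component draws from a purpose-tagged stream derived from
(seed, tag) so that adding a generator step never shifts the draws of an
existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "child_seed"]


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """Return a Generator for the stream identified by (seed, tag)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())]))


def child_seed(seed: int, tag: str) -> int:
    """A derived 31-bit seed for libraries that take plain integer seeds."""
    return int(rng_for(seed, tag).integers(0, 2**31 - 1))
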
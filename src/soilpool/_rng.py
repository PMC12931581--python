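"""Deterministic RNG substream derivation.

Every stochastic stage draws from a `numpy` Generator seeded by a
SeedSequence built from the master seed plus stable integer keys, so results
do not depend on iteration order and any stage can be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "key_of"]


def key_of(token: object) -> int:
    """Map an arbitrary token (str, int, ...) to a stable 32-bit key."""
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    return zlib.crc32(str(token).encode("utf-8"))


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """Return a Generator for stream (seed, *tokens).

    Identical arguments always yield an identically-seeded generator.
    """
    keys = [key_of(t) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))
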
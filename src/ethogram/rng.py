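"""Seed management.

All randomness in the package (bout sampling, sensor noise, the
train/test split, bootstrap bags, split candidates) derives from one
root integer seed through *named sub-streams*, so that each stage is
independently reproducible: changing the noise stream does not perturb
the bout sequence, and vice versa.

A sub-stream is identified by a tuple of strings/ints; the name is
hashed with CRC-32 (stable across platforms and Python versions) and
mixed into a :class:`numpy.random.SeedSequence` together with the root
seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_word(part: str | int) -> int:
    if isinstance(part, int):
        return part & 0xFFFFFFFF
    return zlib.crc32(part.encode("utf-8"))


def substream(seed: int, *name: str | int) -> np.random.Generator:
    """Return a generator for the sub-stream ``name`` of root ``seed``."""
    words = [int(seed) & 0xFFFFFFFF] + [_key_word(p) for p in name]
    return np.random.default_rng(np.random.SeedSequence(words))
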
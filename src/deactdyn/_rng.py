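"""Seed-substream plumbing.

All randomness in the package flows from a single root seed. Each named
consumer (a pipeline stage, a generator) derives its own independent
substream via :func:`substream`, so adding or removing one consumer never
perturbs the draws of any other.

The splitting rule: the substream's ``SeedSequence`` entropy is the pair
``(root_seed, crc32(name))``. CRC32 of the stream name is stable across
processes and Python versions (unlike ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_seed"]


def stream_seed(root_seed: int, name: str) -> list[int]:
    """Entropy pair identifying the substream ``name`` under ``root_seed``."""
    return [int(root_seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for the named consumer."""
    return np.random.default_rng(np.random.SeedSequence(stream_seed(root_seed, name)))
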
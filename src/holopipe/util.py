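"""Seed fan-out and small shared utilities."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive an independent RNG for a named module/stage from one run seed.

    A single pipeline seed fans out to per-stage substreams by stable
    hashing of the stage name (CRC32), so changing one stage's draws never
    perturbs another stage.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
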
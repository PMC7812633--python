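"""Deterministic seed splitting.

Every stochastic choice in the package flows from one master seed through
:func:`rng_for`, which derives an independent child stream from the master
seed plus a tuple of string/int keys. The derivation is stable across runs
and platforms (CRC32 of the repr of each key feeding a SeedSequence).
"""

from __future__ import annotations

import zlib

import numpy as np


def seed_sequence_for(seed: int, *keys) -> np.random.SeedSequence:
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(repr(k).encode()) for k in keys)
    return np.random.SeedSequence(entropy)


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Child generator for the stream identified by ``keys``."""
    return np.random.default_rng(seed_sequence_for(seed, *keys))
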
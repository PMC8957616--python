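"""Deterministic seed derivation.

All randomness in the package flows from a single integer master seed.
Per-stage / per-operation generators are derived by mixing stable string
keys into a :class:`numpy.random.SeedSequence`, so adding a stage never
perturbs the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_sequence(master_seed: int, *keys) -> np.random.SeedSequence:
    """SeedSequence derived from ``master_seed`` and a path of keys."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def child_rng(master_seed: int, *keys) -> np.random.Generator:
    """Generator derived deterministically from (master_seed, *keys)."""
    return np.random.default_rng(child_sequence(master_seed, *keys))
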
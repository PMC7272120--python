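"""Seed handling.

A single session seed is expanded into independent per-component child
seeds through :func:`numpy.random.SeedSequence` spawn keys.  String keys are
hashed with CRC32 so the splitting rule is stable across runs and platforms:
``spawn_rng(seed, "schedule")`` always yields the same stream for a given
``seed``, and streams for distinct key tuples are statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_seed", "spawn_rng"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key)


def spawn_seed(seed: int, *keys: int | str) -> int:
    """Derive a deterministic child seed (< 2**31) from ``seed`` and ``keys``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def spawn_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the child stream ``(seed, *keys)``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))
    return np.random.default_rng(ss)
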
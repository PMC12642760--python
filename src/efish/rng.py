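"""Deterministic random-stream management.

A single root seed is split into named substreams so that adding a new RNG
consumer never perturbs the draws of existing ones.  The split hashes the
stream name (CRC-32) and feeds (root_seed, name_hash, index) into a
``numpy.random.SeedSequence``; all integer seeds surfaced to callers are
masked to 31 bits.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_hash(name: str) -> int:
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def substream(root_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``root_seed``."""
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, _name_hash(name), int(index)])
    return np.random.default_rng(ss)


def child_seed(root_seed: int, name: str, index: int = 0) -> int:
    """Derive a reproducible 31-bit integer seed for the named substream."""
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, _name_hash(name), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
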
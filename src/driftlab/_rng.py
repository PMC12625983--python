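"""Seed fan-out helpers.

A single user-facing seed is expanded into named, statistically independent
substreams (task generation, allocation, drift noise, perturbations, ...) so
that paired experimental arms can consume identical randomness where the
protocol demands it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed", "child_seed"]


def substream_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Derive a named child SeedSequence from a global integer seed."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))


def substream(seed: int, name: str) -> np.random.Generator:
    """A Generator for the named substream of ``seed``."""
    return np.random.default_rng(substream_seed(seed, name))


def child_seed(seed: int, name: str) -> int:
    """A small integer seed (< 2^31) derived from the named substream."""
    return int(substream_seed(seed, name).generate_state(1)[0] % (2**31 - 1))
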
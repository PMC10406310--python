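"""Deterministic seed derivation for every stochastic stage.

Every random draw in the pipeline flows through :func:`rng_for`, which maps a
master seed plus an arbitrary tuple of string/int tokens (subject id, stage
name, iteration index, ...) to an independent ``numpy`` Generator.  Identical
(master seed, tokens) always yield the identical stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "seed_for"]


def seed_for(master_seed: int, *tokens) -> np.random.SeedSequence:
    """Derive a SeedSequence from a master seed and a token path."""
    key = [int(master_seed) & 0x7FFFFFFF]
    for tok in tokens:
        key.append(zlib.crc32(repr(tok).encode("utf8")))
    return np.random.SeedSequence(key)


def rng_for(master_seed: int, *tokens) -> np.random.Generator:
    """Independent Generator for (master seed, token path)."""
    return np.random.default_rng(seed_for(master_seed, *tokens))
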
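"""Deterministic per-stage random streams derived from one global seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(seed: int, *tags) -> int:
    """A child seed (< 2**31) from a global seed and a stage tag."""
    entropy = [int(seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


def derive_rng(seed: int, *tags) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *tags))
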
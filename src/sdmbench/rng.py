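"""Seed handling.

Every stochastic operation accepts either an integer seed or a
``numpy.random.Generator``; batches derive independent per-species
streams from a single master seed via ``SeedSequence`` spawn keys so a
batch can be extended without disturbing earlier species.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng", "derive_seed", "spawn_rng"]


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) for (master seed, index...)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def spawn_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    )
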
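"""Deterministic RNG stream derivation.

One integer master seed; every window / swarm / iteration gets its own
independent stream derived from (seed, *indices) via numpy's SeedSequence
spawn-key mechanism, so results are reproducible and order-independent.
"""
from __future__ import annotations

import numpy as np

__all__ = ["derive_rng", "derive_seed_sequence"]


def derive_seed_sequence(seed: int, *indices: int) -> np.random.SeedSequence:
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(i) for i in indices))


def derive_rng(seed: int, *indices: int) -> np.random.Generator:
    """Generator for the stream identified by (seed, *indices)."""
    return np.random.default_rng(derive_seed_sequence(seed, *indices))
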
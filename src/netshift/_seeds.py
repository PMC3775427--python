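"""Deterministic seed derivation.

One root seed drives every stochastic stage.  Child streams are derived
with :class:`numpy.random.SeedSequence` keyed by a stage/replicate index,
so sweeps can be reproduced pointwise and parallelized without changing
any draw.
"""
from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "as_seed_sequence"]


def child_seed(root: int, *key: int) -> np.random.SeedSequence:
    """Seed for the ``key``-th substream of ``root`` (stable across runs)."""
    return np.random.SeedSequence([int(root), *(int(k) for k in key)])


def as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, (list, tuple)):
        return np.random.SeedSequence([int(s) for s in seed])
    return np.random.SeedSequence(int(seed))
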
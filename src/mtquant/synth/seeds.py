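"""Deterministic sub-seed derivation.

A run has one integer master seed.  Every fixture gets its own sub-seed via
``subseed(master, index)``, which hashes the pair ``[master, index]`` through
``numpy.random.SeedSequence``.  The scheme is a pure function of the two
integers, so fixtures may be generated in any order (or in parallel) and
still be bit-identical to a sequential run.
"""

from __future__ import annotations

import numpy as np

__all__ = ["subseed", "rng_for"]


def subseed(master_seed: int, index: int) -> int:
    """Derive the sub-seed for fixture number ``index`` under ``master_seed``."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0])


def rng_for(master_seed: int, index: int) -> np.random.Generator:
    """Generator seeded with ``subseed(master_seed, index)``."""
    return np.random.default_rng(subseed(master_seed, index))
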
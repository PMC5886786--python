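"""Deterministic seed derivation.

Every stochastic operation takes an explicit integer seed; a master seed
is expanded into per-stage seeds by fixed offsets so whole-pipeline runs
are reproducible from one number.  Derived seeds stay below 2**31.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31


def derive_seed(master: int, offset: int) -> int:
    """Stable child seed from a master seed and a fixed stage offset."""
    return (master * 1_000_003 + offset * 7_919 + 17) % _MOD


def make_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))
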
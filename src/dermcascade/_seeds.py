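"""Deterministic child-seed derivation.

Every randomized stage consumes a child seed derived from the master seed and
a stage label, so pipelines are reproducible end to end from a single integer.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(master: int, label: str) -> int:
    """Derive a stage seed (< 2**31) from a master seed and a stage name."""
    ss = np.random.SeedSequence([int(master) % _MOD, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % _MOD)


def derive_rng(master: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, label))
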
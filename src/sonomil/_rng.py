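"""Named random-number streams fanned out from one integer seed.

One experiment seed must reproduce every stochastic component independently
(cohort split, weight init, dropout, augmentation, batch shuffling), so each
component draws from a stream derived from ``(seed, name)`` rather than from a
single shared generator whose state would couple them.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """Deterministic 31-bit seed for the named substream of ``seed``."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent ``numpy`` generator for the named substream of ``seed``."""
    return np.random.default_rng(substream_seed(seed, name))
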
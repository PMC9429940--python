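"""Deterministic seed derivation.

One top-level integer seed expands to per-stage seeds through a stable
BLAKE2 hash of ``"{seed}:{label}"`` so each stage is independently
re-runnable and every derived seed fits in a signed 32-bit integer.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, label: str) -> int:
    digest = hashlib.blake2b(f"{master}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def rng_for(master: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, label))
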
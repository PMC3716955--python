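"""Seed-substream derivation.

All stochastic stages derive their own 31-bit seed from the single run seed
and a stage label, so any stage can be re-run in isolation and still produce
the bytes it produced inside a full pipeline run.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, label: str) -> int:
    """Deterministically derive a 31-bit child seed from (seed, label)."""
    digest = hashlib.sha256(f"{int(seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(seed: int, label: str) -> np.random.Generator:
    """A numpy Generator seeded by the (seed, label) substream."""
    return np.random.default_rng(derive_seed(seed, label))
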
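"""Deterministic seed fan-out.

A single run seed is expanded into per-fold / per-operator / per-generation
seeds by hashing a label path, so adding folds or operators never reshuffles
the streams of earlier ones.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, *path) -> int:
    """Stable 32-bit seed derived from a master seed and a label path."""
    key = ":".join([str(int(master))] + [str(p) for p in path])
    digest = hashlib.blake2b(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def derive_rng(master: int, *path) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *path))
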
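"""Small shared helpers: seed derivation and standardization."""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific seed from the master seed.

    Hash-based so stages are reproducible in isolation and statistically
    independent of each other; result fits in 31 bits.
    """
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


def standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit SD (population/ddof=0 convention)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
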
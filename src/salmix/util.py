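"""Shared helpers: seed fan-out and simplex checks."""

from __future__ import annotations

import hashlib
from collections.abc import Iterable

import numpy as np

__all__ = ["substream_seed", "rng_for", "check_simplex"]


def substream_seed(master: int, *tokens: object) -> int:
    """Derive a reproducible sub-seed from a master seed and purpose tokens.

    Hashing ``(master, *tokens)`` gives independent streams per purpose and
    unit, so adding a new stream never shifts an existing one.  The result
    fits in 31 bits.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(repr((int(master),) + tuple(str(t) for t in tokens)).encode())
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


def rng_for(master: int, *tokens: object) -> np.random.Generator:
    """Generator seeded from :func:`substream_seed`."""
    return np.random.default_rng(substream_seed(master, *tokens))


def check_simplex(p: Iterable[float], tol: float = 1e-9, name: str = "proportions") -> np.ndarray:
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if np.any(p < -tol):
        raise ValueError(f"{name} must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
    return np.clip(p, 0.0, None)
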
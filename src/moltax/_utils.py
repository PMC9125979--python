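"""Small shared helpers: seed derivation and input validation."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a stable 31-bit child seed from a master seed and string tokens.

    CRC32-based so that the mapping is identical across processes and Python
    versions (unlike :func:`hash`).  Used to give every (signature, endotype)
    cell of the drug-scoring matrix its own reproducible permutation stream,
    independent of evaluation order.
    """
    payload = "|".join([str(int(master))] + [str(t) for t in tokens])
    return zlib.crc32(payload.encode("utf-8")) & 0x7FFFFFFF


def check_probabilities(p, name: str = "pvals") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return p


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
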
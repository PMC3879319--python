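"""Deterministic seed derivation.

Per-probe and per-target training seeds are keyed by probe *identity*
(via crc32 of the ID string), never by position, so probe ordering cannot
change any score — a requirement for comparable, permutation-invariant
results.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(*parts: int | str) -> int:
    """Mix integers and strings into one reproducible 32-bit seed."""
    entropy = [
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) & 0xFFFFFFFF
        for p in parts
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])
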
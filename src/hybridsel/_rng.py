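"""Deterministic per-stage random generators derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master: int, *stage: str | int) -> np.random.SeedSequence:
    """SeedSequence for a named pipeline stage.

    Stage names are hashed with CRC-32 so each stage draws from an
    independent, reproducible stream regardless of call order.
    """
    key = tuple(
        zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in stage
    )
    return np.random.SeedSequence(entropy=int(master), spawn_key=key)


def rng_for(master: int, *stage: str | int) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *stage))
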
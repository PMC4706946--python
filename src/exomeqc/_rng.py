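"""Deterministic named random substreams.

Every stochastic operation in the package draws from a substream derived
from one global integer seed plus a short stream name, so modules can be
exercised independently without perturbing each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, name).

    The name is hashed with CRC-32 so the mapping is stable across runs
    and platforms.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
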
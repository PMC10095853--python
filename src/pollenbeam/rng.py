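"""Named random substreams.

All pipeline randomness flows from one integer seed.  Each stage draws from
its own named substream so that re-running a single stage with the same seed
reproduces it exactly regardless of what the other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _key_to_int(key: str) -> int:
    return zlib.crc32(key.encode("utf-8"))


def substream(seed: int, key: str) -> np.random.Generator:
    """A generator for the substream named ``key`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence((seed, _key_to_int(key))))


def subseed(seed: int, key: str) -> int:
    """A derived integer seed (< 2**31) for the named substream."""
    ss = np.random.SeedSequence((seed, _key_to_int(key)))
    return int(ss.generate_state(1)[0] % (2**31))
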
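"""Deterministic per-stage random streams.

Every stochastic operation in the package derives its generator from a
single master seed plus a stage name, so any stage can be re-run in
isolation and reproduce its output bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed on ``(master_seed, name)``.

    The stage name is folded into the seed sequence through a CRC32 of
    its UTF-8 bytes, which keeps streams for different stages
    statistically independent while remaining stable across platforms
    and Python versions (unlike ``hash``).
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))
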
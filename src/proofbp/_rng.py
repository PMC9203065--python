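"""Named random substreams.

A single master seed fans out to independent, reproducible generators, one
per named stage ("covariates", "kfold-select-sbp", ...), so any stage can be
re-run in isolation and still produce the bytes it produced inside the full
pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator deterministically derived from (seed, name)."""
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)
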
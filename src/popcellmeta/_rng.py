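"""Seed-stream management.

All randomness in the package flows from one user-supplied integer seed.
Stages derive independent substreams by hashing their stage name into a
``numpy.random.SeedSequence`` spawn key, so toggling one stage never perturbs
the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for `stage` derived deterministically from `seed`."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def check_seed(seed: int) -> int:
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return int(seed)
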
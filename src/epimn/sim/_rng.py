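"""Seed-stable substream derivation for the generators.

Each generator (and each internal stage) derives its RNG from the run seed
plus a stable CRC32 hash of the stage name, so adding or reordering stages
never perturbs another stage's draws and every output is bit-reproducible
given (seed, parameters).
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, stage: str) -> np.random.Generator:
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))
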
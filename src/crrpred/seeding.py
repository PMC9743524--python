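"""Deterministic fan-out of one master seed into per-stage seeds.

Every stochastic stage receives its own seed derived from the master
seed and a stage name, so stages can be re-run in isolation and whole
runs are bit-reproducible. Derived seeds stay below 2**31.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    entropy = [int(master_seed), zlib.crc32(stage.encode())]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)
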
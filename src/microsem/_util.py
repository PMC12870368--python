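"""Small shared helpers: seed derivation and float formatting."""

from __future__ import annotations

import zlib

import numpy as np

# All numeric text output is pinned to 12 significant digits so that
# re-running a stage with identical seeds is byte-identical.
FLOAT_FMT = "%.12g"


def format_float(x: float) -> str:
    return FLOAT_FMT % float(x)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31.

    Mixing the stage name through CRC32 keeps stage streams independent of
    each other and of the order stages run in.
    """
    mix = zlib.crc32(stage.encode("utf-8"))
    return int((int(global_seed) * 1000003 + mix) % (2**31 - 1))


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, stage))
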
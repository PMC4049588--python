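"""Named, independent random substreams under a single root seed.

Every generator in the package draws from a stream derived from the root
seed and a stable string name, so adding a new generator (or reordering
calls) never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the stream ``name`` under root ``seed``.

    The stream key is a CRC32 of the name, folded into the SeedSequence
    spawn key; streams with distinct names are statistically independent.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    )
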
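"""Named random substreams derived from a single master seed.

Every generator in :mod:`dmlkit.simulate` draws from its own substream so that
one stage can be regenerated without replaying the others, while the whole
simulation stays a pure function of the master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``.

    The stream key is a CRC32 of the name, so streams are stable across
    sessions and independent of call order.
    """
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,)))
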
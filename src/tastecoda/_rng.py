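"""Deterministic random-stream derivation.

A single global seed is expanded into independent substreams keyed by
arbitrary labels (group, animal, day, purpose).  Streams are derived from
the key contents, not from call order, so e.g. adding an animal to a
cohort never perturbs the streams of existing animals.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_u32(key: object) -> int:
    return zlib.crc32(repr(key).encode("utf-8")) & 0xFFFFFFFF


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a ``numpy` Generator`` for the substream named by ``keys``.

    The stream depends only on ``seed`` and the key values themselves.
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [_key_to_u32(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
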
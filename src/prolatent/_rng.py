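"""Seed fan-out.

A single user-facing seed is expanded into independent, named substreams so
that toggling one stochastic stage (e.g. condition dropout) never perturbs
another (e.g. parameter init).
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is derived from a CRC32 of the name, so the mapping is
    stable across processes and python versions.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
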
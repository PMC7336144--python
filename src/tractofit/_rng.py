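"""Seed plumbing: every source of randomness derives from one integer seed
through named substreams, so pipelines are reproducible end to end."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Distinct names give statistically independent streams; the mapping is
    stable across runs and platforms.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
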
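"""Seed handling: one global seed, independent per-stage substreams.

Substreams are derived from (seed, label) so that adding a new stage to a
pipeline never perturbs the random numbers any existing stage sees.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``label``.

    The stream depends only on (seed, label), not on how many other
    substreams were created before it.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def spawn_int(seed: int, label: str) -> int:
    """A derived integer seed < 2**31 for APIs that want a plain int."""
    return int(substream(seed, label).integers(0, 2**31 - 1))
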
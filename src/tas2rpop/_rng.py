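"""Named-substream random number generators.

A single top-level integer seed is expanded into independent substreams
keyed by a text label (e.g. one per gene, one per pipeline stage), so that
adding a gene or toggling a stage never perturbs the random numbers another
consumer sees.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the substream named ``label`` under ``seed``.

    The same (seed, label) pair always yields the same stream; distinct
    labels yield statistically independent streams.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,)))
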
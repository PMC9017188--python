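"""Seeded stream splitting.

Every stochastic operation in the package draws from a named substream of a
single integer master seed, so that (a) identical seeds give byte-identical
output across runs and platforms, and (b) paired simulations (e.g. the same
ground truth acquired at different boost loadings) can share the substreams
that must coincide while differing in the ones that must not.

A substream is identified by the master seed plus one or more string labels;
labels are hashed with CRC-32 (stable across platforms, unlike ``hash``) and
fed to :class:`numpy.random.SeedSequence` as extra entropy words.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    words = [int(seed)] + [zlib.crc32(lab.encode("utf-8")) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(words))
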
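"""Seed-derivation helpers.

Every stochastic operation in the package takes either a
:class:`numpy.random.Generator` or an integer seed.  Named substreams are
derived from a single root seed so that independent components (segregation
draws, population simulation, measurement noise, ABC proposals, ...) never
share a stream, while the whole pipeline stays reproducible from one integer.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "substream", "as_generator"]


def _tag_int(tag) -> int:
    return zlib.crc32(str(tag).encode("utf-8"))


def child_seed(seed: int, *tags) -> int:
    """Derive a deterministic child seed (< 2**31) from ``seed`` and tags."""
    ss = np.random.SeedSequence([int(seed)] + [_tag_int(t) for t in tags])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, *tags) -> np.random.Generator:
    """A Generator on the named substream of ``seed``."""
    return np.random.default_rng(child_seed(seed, *tags))


def as_generator(rng) -> np.random.Generator:
    """Accept a Generator or a seed-like and return a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
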
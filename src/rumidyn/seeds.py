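"""Deterministic seed splitting.

Every source of randomness in the package derives from a single master seed
through ``numpy.random.SeedSequence`` keyed by an integer path, so any piece
of a large experiment (one cohort, one replicate of one scenario group) can
be regenerated in isolation:

    rng = child_rng(master_seed, group_index, replicate_index)

Two different paths from the same master seed give statistically
independent, reproducible streams.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seq", "child_rng"]


def child_seq(master: int | None, *path: int) -> np.random.SeedSequence:
    if master is None:
        return np.random.SeedSequence()
    return np.random.SeedSequence((int(master), *[int(p) for p in path]))


def child_rng(master: int | None, *path: int) -> np.random.Generator:
    """A PCG64 generator for the stream addressed by ``(master, *path)``."""
    return np.random.default_rng(child_seq(master, *path))
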
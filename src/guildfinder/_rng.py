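"""Seed-splitting helpers.

All stochastic operations in the package are pure functions of their inputs
and a seed.  Experiments derive independent child streams from one master
seed through :class:`numpy.random.SeedSequence` spawn keys, so that e.g. the
species pool, per-sample memberships and per-sample measurement noise never
share a stream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_rng(seed: int | None, *path: int) -> np.random.Generator:
    """Return a generator for the stream identified by ``(seed, *path)``.

    ``path`` is a tuple of small non-negative integers naming the stream
    (e.g. ``(replicate, STREAM_NOISE)``).  The same ``(seed, path)`` always
    yields the same stream; distinct paths yield independent streams.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(path)))


def child_seed(seed: int | None, *path: int) -> int:
    """A 31-bit integer seed derived from ``(seed, *path)``.

    Used where a third-party API (e.g. scikit-learn) wants an ``int`` seed.
    """
    if seed is None:
        seed = np.random.SeedSequence().entropy % (2**31)
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(path))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))
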
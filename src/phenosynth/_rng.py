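"""Deterministic RNG stream splitting.

Every stochastic operation in the package takes either an integer seed or
a :class:`numpy.random.Generator`. Collections of items derive one
independent stream per (seed, index) pair via ``SeedSequence`` spawning,
so generating item 7 alone yields the same bytes as generating items
0..9 and keeping the 8th.
"""

from __future__ import annotations

import numpy as np

__all__ = ["stream", "substream_seed", "as_generator"]


def stream(seed: int, *keys: int) -> np.random.Generator:
    """Return a Generator for the stream identified by (seed, *keys)."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def substream_seed(seed: int, *keys: int) -> int:
    """Derive a plain integer seed (< 2**31) for APIs that want one."""
    ss = np.random.SeedSequence([int(seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


def as_generator(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(int(seed_or_rng))
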
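"""Deterministic seed-splitting helpers.

All stochastic operations in the package derive their generators from a
single master seed via ``numpy.random.SeedSequence`` spawn keys, so any
subset of neurons / stimuli / repeats is reproducible independent of
iteration order.
"""

from __future__ import annotations

import numpy as np

# fixed tags keep substreams for different purposes disjoint
_TAGS = {
    "population": 1,
    "gate": 2,
    "counts": 3,
    "bins": 4,
    "grating": 5,
    "decode": 6,
    "stimuli": 7,
}


def substream(master_seed: int, tag: str, *indices: int) -> np.random.Generator:
    """Return a Generator for (master_seed, tag, *indices).

    The same arguments always yield the same stream; distinct arguments
    yield statistically independent streams.
    """
    key = (_TAGS[tag],) + tuple(int(i) for i in indices)
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=key))
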
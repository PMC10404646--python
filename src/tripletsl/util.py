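"""Small shared helpers."""
from __future__ import annotations

import numpy as np

RngLike = "int | None | np.random.Generator | np.random.SeedSequence"


def as_rng(seed=None) -> np.random.Generator:
    """Return a numpy Generator from an int seed, SeedSequence, Generator or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """Deterministically derive ``n`` independent child seed sequences."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return ss.spawn(n)
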
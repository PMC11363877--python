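"""Small internal helpers shared across modules."""
from __future__ import annotations

import numpy as np


def as_rng(seed) -> np.random.Generator:
    """Return a numpy Generator from an int seed, SeedSequence, or existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
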
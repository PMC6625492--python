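"""Small internal helpers."""

import numpy as np


def as_seedseq(seed) -> np.random.SeedSequence:
    """Normalise an int / None / SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def seed_int(seedseq) -> int:
    """A single sub-2³¹ integer seed derived from a SeedSequence."""
    return int(as_seedseq(seedseq).generate_state(1)[0] % (2**31))
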
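"""Deterministic RNG derivation.

One root seed per run; every consumer derives its own stream from the root
seed plus integer context keys (e.g. the stimulus orientation in
millidegrees), so per-stimulus streams do not depend on grid order or on how
many draws other stimuli consumed.
"""

from __future__ import annotations

import numpy as np

# Fixed namespace keys keeping independent purposes on independent streams.
KEY_MEASUREMENT = 11
KEY_SHUFFLE = 23
KEY_ARBITRARY = 37
KEY_FIT = 53


def stimulus_key(value: float) -> int:
    """Integer key for an angle/stimulus, at millidegree resolution."""
    return int(round(float(value) * 1000.0))


def rng_for(seed: int, *keys: int) -> np.random.Generator:
    """Generator derived from a root seed and integer context keys.

    Keys (and the seed) are reduced into uint32 space, so negative context
    keys such as angles below the reference are valid.
    """
    entropy = [int(k) % (2 ** 32) for k in (seed, *keys)]
    return np.random.default_rng(np.random.SeedSequence(entropy))
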
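"""Stable derivation of per-purpose random seeds from one global seed.

Every stochastic operation takes its own seed derived from the run's global
seed plus a purpose string (and optionally an id), via a cryptographic hash.
This keeps parallel streams independent and runs reproducible regardless of
call order.
"""

import hashlib

import numpy as np


def derive_seed(seed: int, *labels: object) -> int:
    """Map (seed, labels...) to a stable 31-bit seed."""
    key = ":".join([str(int(seed))] + [str(l) for l in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(seed: int, *labels: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *labels))
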
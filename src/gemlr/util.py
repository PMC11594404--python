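"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def derive_seed(*keys: int) -> int:
    """Deterministic child seed from a tuple of integer keys (< 2^31).

    All randomness in the package flows from one top-level seed through
    named substreams, so that runs are bit-reproducible and substreams
    (initialization, folds, oversampling, simulation) do not collide.
    """
    ss = np.random.SeedSequence([int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2 ** 31))
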
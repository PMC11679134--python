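"""Seeded random-stream management.

One master seed spawns independent, purpose-keyed substreams so that
changing how one stage consumes randomness (e.g. the masking schedule)
never perturbs another stage (e.g. the weight initialization).
"""

from __future__ import annotations

import numpy as np

# Fixed purpose keys: appending new purposes keeps old streams stable.
_PURPOSES = {
    "phantom": 1,
    "noise1": 2,
    "noise2": 3,
    "masking": 4,
    "weights": 5,
    "dip_input": 6,
    "corruption": 7,
    "dropout": 8,
    "prediction": 9,
}


def substream(master_seed: int, purpose: str) -> np.random.Generator:
    """Return an independent generator for ``purpose`` under ``master_seed``."""
    if purpose not in _PURPOSES:
        raise KeyError(
            f"unknown rng purpose {purpose!r}; known: {sorted(_PURPOSES)}"
        )
    seq = np.random.SeedSequence([int(master_seed), _PURPOSES[purpose]])
    return np.random.default_rng(seq)
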
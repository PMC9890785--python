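"""Named, hierarchical random streams.

All stochastic stages (cohort draw, person splits, folds, bootstrap
replicates, tree growing) derive an independent integer seed from one root
seed plus a tuple of string/int tokens, so changing e.g. the number of
bootstrap replicates never perturbs the cohort draw, and any single
replicate can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def seed_for(root_seed: int, *tokens) -> int:
    """Deterministic child seed (< 2**31) for a named stream."""
    label = "|".join([str(int(root_seed)), *(str(t) for t in tokens)])
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % MAX_SEED


def rng_for(root_seed: int, *tokens) -> np.random.Generator:
    """Generator seeded by :func:`seed_for`."""
    return np.random.default_rng(seed_for(root_seed, *tokens))
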
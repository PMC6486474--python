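"""Seeded random-number streams.

One master seed drives the whole simulator. Each omics layer draws from its
own independent stream derived from that seed, so adding or removing a layer
never perturbs the draws of another layer.
"""

from __future__ import annotations

import numpy as np

# Fixed spawn keys per layer; appending new labels is safe, reordering is not.
_MODULE_KEYS = {
    "fixtures": 1,
    "genomics": 2,
    "phenotype": 3,
    "methylation": 4,
    "transcriptomics": 5,
    "proteomics": 6,
    "validation": 7,
    "scenario": 8,
}


def module_rng(master_seed: int, module: str) -> np.random.Generator:
    """Return the independent RNG stream for one simulator layer."""
    if module not in _MODULE_KEYS:
        raise KeyError(f"unknown module stream: {module!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_MODULE_KEYS[module],))
    return np.random.default_rng(ss)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept either a seed or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
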
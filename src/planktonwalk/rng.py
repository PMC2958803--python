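"""Seed management.

One externally supplied integer seed drives every stage of the pipeline.
Stage streams are derived with :class:`numpy.random.SeedSequence` spawn
keys, which are stable across numpy versions, so each stage (library
generation, simulation replicates, virtual sampling) is independently
reproducible: re-running one stage with the same top-level seed gives
bit-identical output no matter what the other stages did.
"""

from __future__ import annotations

import numpy as np

#: fixed spawn-key slot per pipeline stage
STAGE_KEYS = {
    "library": 1,
    "sim": 2,
    "sampling": 3,
    "metrics": 4,
}


def stage_seed_sequence(seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """SeedSequence for a named stage (and sub-index, e.g. a replicate)."""
    if stage not in STAGE_KEYS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(STAGE_KEYS)}")
    return np.random.SeedSequence(int(seed), spawn_key=(STAGE_KEYS[stage], int(index)))


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for a named stage, derived from the top-level seed."""
    return np.random.default_rng(stage_seed_sequence(seed, stage, index))
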
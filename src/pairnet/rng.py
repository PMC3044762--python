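"""Seed discipline: one master seed, named child streams.

Every source of randomness in the pipeline (structure, cell parameters,
initial weights, input spike trains, integration noise, trial ordering,
decision-layer noise) draws from its own child stream derived from the
master seed by a fixed (stream, index) scheme, so each source is
independently reproducible.
"""

from __future__ import annotations

import numpy as np

# fixed stream ids -- never renumber, serialized runs depend on them
STRUCTURE = 0
CELL_PARAMS = 1
WEIGHTS = 2
INPUTS = 3
NOISE = 4
TRIALS = 5
DECISION = 6
REWARD = 7
GRID = 8


def child_rng(master_seed: int, stream: int, index: int = 0) -> np.random.Generator:
    """Generator for a named randomness source under ``master_seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(stream), int(index)]))


def child_seed(master_seed: int, stream: int, index: int = 0) -> int:
    """A plain integer seed (< 2**31) derived from the same scheme."""
    ss = np.random.SeedSequence([int(master_seed), int(stream), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
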
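"""Deterministic, independent random streams derived from one master seed.

Each consumer of randomness gets its own ``numpy`` Generator keyed by
``(master_seed, stream_id)``. Per-unit spike streams use ids offset by
``UNIT_STREAM_BASE`` so adding units to a session never perturbs the spike
trains of existing units.
"""

from __future__ import annotations

import numpy as np

SCHEDULE_STREAM = 1
BEHAVIOR_STREAM = 2
GROUND_TRUTH_STREAM = 3
KINEMATICS_STREAM = 4
CONTINUOUS_STREAM = 5
UNIT_STREAM_BASE = 100_000
UNIT_TRAIT_STREAM_BASE = 200_000


def stream(master_seed: int, stream_id: int) -> np.random.Generator:
    """Return the Generator for one named stream of a master seed."""
    return np.random.default_rng([int(master_seed), int(stream_id)])


def unit_stream(master_seed: int, unit_index: int) -> np.random.Generator:
    """Independent spike-generation stream for one unit."""
    return stream(master_seed, UNIT_STREAM_BASE + int(unit_index))


def unit_trait_stream(master_seed: int, unit_index: int) -> np.random.Generator:
    """Independent stream for one unit's latent traits (rate, tuning)."""
    return stream(master_seed, UNIT_TRAIT_STREAM_BASE + int(unit_index))
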
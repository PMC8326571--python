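"""Synthetic joint-angle kinematics with object-specific grasp postures.

Each object has a canonical settled-grasp posture in joint-angle space; a
trial's realized posture is the canonical posture, plus a fixed offset
vector on tactile trials (zero by default — grips are modality independent),
plus Gaussian posture noise. The hand travels from the rest posture to the
grasp posture along a minimum-jerk trajectory during the movement epoch and
holds the grasp posture until the end of the hold period. Samples carry
independent Gaussian sensor noise and are taken at a glove rate drawn once
per session from the configured range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import GeneratorSettings, TaskConfig
from ..types import GroundTruth, KinematicTrace
from ._rng import KINEMATICS_STREAM, stream


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1] (zero end velocities)."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def trial_posture(
    ground_truth: GroundTruth,
    obj_index: int,
    modality: str,
    rng: np.random.Generator,
    noise_deg: float,
) -> np.ndarray:
    """Settled grasp posture for one trial."""
    posture = ground_truth.canonical_postures[obj_index].copy()
    if modality == "tactile":
        posture = posture + ground_truth.modality_offset
    if noise_deg > 0:
        posture = posture + rng.normal(0.0, noise_deg, posture.shape)
    return posture


def simulate_kinematics(
    trials: pd.DataFrame,
    ground_truth: GroundTruth,
    cfg: TaskConfig,
    gen: GeneratorSettings,
    seed: int,
) -> list[KinematicTrace]:
    """Generate one joint-angle trace per trial."""
    rng = stream(seed, KINEMATICS_STREAM)
    glove_rate = float(rng.uniform(*cfg.glove_rate_hz_range))
    dt = 1000.0 / glove_rate
    objects = list(cfg.objects)
    rest = ground_truth.rest_posture
    traces: list[KinematicTrace] = []
    for _, trial in trials.iterrows():
        posture = trial_posture(
            ground_truth,
            objects.index(trial["object"]),
            trial["modality"],
            rng,
            gen.posture_noise_deg,
        )
        t0 = float(trial["trial_start"])
        t1 = float(trial["hold_end"])
        mo = float(trial["movement_onset"])
        lift = float(trial["object_lifted"])
        times = np.arange(t0, t1, dt)
        tau = (times - mo) / max(lift - mo, 1e-9)
        s = minimum_jerk(tau)[:, None]
        angles = rest[None, :] + s * (posture - rest)[None, :]
        if gen.sensor_noise_deg > 0:
            angles = angles + rng.normal(0.0, gen.sensor_noise_deg, angles.shape)
        traces.append(
            KinematicTrace(trial_id=int(trial["trial_id"]), times=times, angles=angles)
        )
    return traces
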
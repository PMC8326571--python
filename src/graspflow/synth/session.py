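"""Full synthetic-session assembly with stored ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import AREAS, EPOCHS, GeneratorSettings, TaskConfig
from ..types import GroundTruth, Session
from ._rng import GROUND_TRUTH_STREAM, stream, unit_trait_stream
from .continuous import simulate_continuous
from .kinematics import simulate_kinematics
from .schedule import draw_condition_schedule, simulate_behavior_times
from .spikes import simulate_spike_trains


def make_ground_truth(
    cfg: TaskConfig, gen: GeneratorSettings, seed: int
) -> GroundTruth:
    """Draw the latent session structure: units, tuning gains, postures.

    Tuned/untuned assignment is Bernoulli per unit and factor; untuned units
    get tuning gains of exactly zero in every epoch. Canonical grasp
    postures are drawn uniformly per joint, which in a high-dimensional
    angle space yields well-separated, object-specific grips.

    Each unit's latent traits come from its own random stream, so enlarging
    the population leaves the traits (and hence spike trains) of existing
    units unchanged.
    """
    rng = stream(seed, GROUND_TRUTH_STREAM)
    areas = [a for a in AREAS if a in gen.unit_counts]
    unit_ids: list[str] = []
    unit_areas: list[str] = []
    for area in areas:
        for i in range(gen.unit_counts[area]):
            unit_ids.append(f"{area}_{i:03d}")
            unit_areas.append(area)
    n_units = len(unit_ids)

    lo, hi = gen.baseline_rate_range_hz
    baseline = np.empty(n_units)
    object_tuned = np.empty(n_units, dtype=bool)
    modality_tuned = np.empty(n_units, dtype=bool)
    object_pref = np.empty((n_units, cfg.n_objects))
    for i in range(n_units):
        rng_u = unit_trait_stream(seed, i)
        baseline[i] = rng_u.uniform(lo, hi)
        object_tuned[i] = rng_u.random() < gen.object_tuned_fraction
        modality_tuned[i] = rng_u.random() < gen.modality_tuned_fraction
        object_pref[i] = rng_u.uniform(-1.0, 1.0, cfg.n_objects)

    obj_profile = np.array([gen.object_profile[e] for e in EPOCHS])
    mod_profile = np.array([gen.modality_profile[e] for e in EPOCHS])
    object_gain = np.where(
        object_tuned[:, None], gen.object_gain * obj_profile[None, :], 0.0
    )
    modality_gain = np.where(
        modality_tuned[:, None], gen.modality_gain * mod_profile[None, :], 0.0
    )

    clo, chi = gen.canonical_range_deg
    canonical = rng.uniform(clo, chi, (cfg.n_objects, gen.posture_dim))
    direction = rng.normal(size=gen.posture_dim)
    direction /= np.linalg.norm(direction)
    modality_offset = gen.modality_offset_deg * direction

    unit_table = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "area": unit_areas,
            "baseline_hz": baseline,
            "object_tuned": object_tuned,
            "modality_tuned": modality_tuned,
        }
    )
    timing = {
        "grasp_rt_mean_ms": gen.grasp_rt_mean_ms,
        "grasp_rt_sigma": gen.grasp_rt_sigma,
        "grasp_mt_mean_ms": dict(gen.grasp_mt_mean_ms),
        "grasp_mt_sigma": gen.grasp_mt_sigma,
        "exploration_rt_mean_ms": gen.exploration_rt_mean_ms,
        "exploration_rt_sigma": gen.exploration_rt_sigma,
        "exploration_mt_mean_ms": gen.exploration_mt_mean_ms,
        "exploration_mt_sigma": gen.exploration_mt_sigma,
    }
    artifact = {
        "gain": gen.artifact_gain,
        "drift_amp_uv": gen.drift_amp_uv,
        "burst_rate_hz": gen.burst_rate_hz,
        "burst_amp_uv": gen.burst_amp_uv,
    }
    return GroundTruth(
        master_seed=int(seed),
        unit_table=unit_table,
        object_gain=object_gain,
        modality_gain=modality_gain,
        object_pref=object_pref,
        epoch_rate_gain=dict(gen.epoch_rate_gain),
        canonical_postures=canonical,
        modality_offset=modality_offset,
        rest_posture=np.full(gen.posture_dim, gen.rest_angle_deg),
        timing=timing,
        artifact=artifact,
    )


def generate_session(
    cfg: TaskConfig | None = None,
    gen: GeneratorSettings | None = None,
    seed: int = 0,
    continuous: bool = False,
    spikes: bool = True,
    kinematics: bool = True,
) -> Session:
    """Generate one complete synthetic session.

    Identical ``(cfg, gen, seed)`` always yield identical sessions: every
    randomized component draws from its own stream keyed by the master seed,
    and per-unit spike streams are keyed by unit index.

    ``continuous`` additionally renders the spike trains into a broadband
    recording; this is memory-hungry (30 kS/s per channel) and intended for
    short sessions.
    """
    cfg = cfg or TaskConfig()
    gen = gen or GeneratorSettings()
    schedule, counts = draw_condition_schedule(cfg, seed)
    trials = simulate_behavior_times(schedule, cfg, gen, seed)
    ground_truth = make_ground_truth(cfg, gen, seed)
    spike_data = (
        simulate_spike_trains(trials, ground_truth, cfg, gen, seed) if spikes else None
    )
    traces = (
        simulate_kinematics(trials, ground_truth, cfg, gen, seed) if kinematics else []
    )
    rec = None
    if continuous:
        if spike_data is None:
            raise ValueError("continuous simulation requires spike trains")
        rec = simulate_continuous(spike_data, cfg, gen, seed)
    ground_truth.timing["condition_counts"] = {
        f"{o}|{m}": c for (o, m), c in counts.items()
    }
    return Session(
        trials=trials,
        spikes=spike_data,
        kinematics=traces,
        continuous=rec,
        ground_truth=ground_truth,
        config=cfg,
        generator=gen,
    )
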
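"""Condition schedule and behavioral event times for synthetic sessions.

The schedule interleaves the 12 conditions (6 objects x 2 modalities) in a
random order, with per-condition trial counts drawn from the configured
range. Reaction and movement times are log-normal with means calibrated to
the behavioral results the generator emulates; all trials are generated as
correct, with event timestamps that respect the paradigm's epoch order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import ConfigError, GeneratorSettings, TaskConfig
from ..types import TRIAL_COLUMNS
from ._rng import BEHAVIOR_STREAM, SCHEDULE_STREAM, stream

_MAX_RESAMPLE = 1000


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Log-normal sample with the given arithmetic mean.

    With sigma == 0 the value is exactly the mean (degenerate distribution).
    """
    if mean <= 0:
        raise ConfigError("log-normal mean must be positive")
    if sigma == 0:
        return float(mean)
    mu = np.log(mean) - 0.5 * sigma**2
    return float(rng.lognormal(mu, sigma))


def _lognormal_capped(
    rng: np.random.Generator, mean: float, sigma: float, cap: float
) -> float:
    """Log-normal sample resampled to stay strictly below ``cap``."""
    for _ in range(_MAX_RESAMPLE):
        x = _lognormal(rng, mean, sigma)
        if x < cap:
            return x
    return min(mean, cap * 0.99)


def draw_condition_schedule(
    cfg: TaskConfig, seed: int
) -> tuple[list[tuple[str, str]], dict[tuple[str, str], int]]:
    """Draw per-condition trial counts and a random interleaving.

    Returns the trial-ordered list of (object, modality) pairs and the
    per-condition counts that produced it.
    """
    rng = stream(seed, SCHEDULE_STREAM)
    lo, hi = cfg.trials_per_condition_range
    conditions = [(o, m) for o in cfg.objects for m in cfg.modalities]
    counts = {c: int(rng.integers(lo, hi + 1)) for c in conditions}
    pool: list[tuple[str, str]] = []
    for c in conditions:
        pool.extend([c] * counts[c])
    order = rng.permutation(len(pool))
    return [pool[i] for i in order], counts


def simulate_behavior_times(
    schedule: list[tuple[str, str]],
    cfg: TaskConfig,
    gen: GeneratorSettings,
    seed: int,
) -> pd.DataFrame:
    """Lay out event timestamps for every scheduled trial.

    Trials are placed sequentially with ``gen.intertrial_ms`` between them.
    Visual trials get a fixed-length cue; tactile trials get a fixed-length
    exploration epoch (``gen.tactile_cue_ms``) containing handrest release,
    exploration lift and return events. Grasp reaction times are resampled
    to fit the go window, so every generated trial is a correct trial.
    """
    if gen.tactile_cue_ms > cfg.tactile_cue_max_ms:
        raise ConfigError(
            "tactile_cue_ms exceeds the paradigm's maximum exploration duration"
        )
    rng = stream(seed, BEHAVIOR_STREAM)
    rows = []
    t = 0.0
    mem_lo, mem_hi = cfg.memory_ms_range
    for trial_id, (obj, modality) in enumerate(schedule):
        trial_start = t
        cue_on = trial_start + cfg.baseline_ms
        if modality == "visual":
            expl_onset = expl_lift = handrest_return = np.nan
            cue_off = cue_on + cfg.visual_cue_ms
        else:
            budget = gen.tactile_cue_ms - gen.exploration_return_ms
            while True:
                expl_rt = _lognormal(
                    rng, gen.exploration_rt_mean_ms, gen.exploration_rt_sigma
                )
                expl_mt = _lognormal(
                    rng, gen.exploration_mt_mean_ms, gen.exploration_mt_sigma
                )
                if expl_rt + expl_mt < budget:
                    break
            expl_onset = cue_on + expl_rt
            expl_lift = expl_onset + expl_mt
            handrest_return = expl_lift + gen.exploration_return_ms
            cue_off = cue_on + gen.tactile_cue_ms
        memory_start = cue_off
        memory_ms = float(rng.uniform(mem_lo, mem_hi))
        go = memory_start + memory_ms
        rt = _lognormal_capped(
            rng, gen.grasp_rt_mean_ms, gen.grasp_rt_sigma, cfg.go_window_ms
        )
        mt = _lognormal(rng, gen.grasp_mt_mean_ms[modality], gen.grasp_mt_sigma)
        movement_onset = go + rt
        object_lifted = movement_onset + mt
        hold_end = object_lifted + cfg.hold_ms
        rows.append(
            dict(
                trial_id=trial_id,
                object=obj,
                modality=modality,
                trial_start=trial_start,
                cue_on=cue_on,
                expl_movement_onset=expl_onset,
                exploration_lift=expl_lift,
                handrest_return=handrest_return,
                cue_off=cue_off,
                memory_start=memory_start,
                go=go,
                movement_onset=movement_onset,
                object_lifted=object_lifted,
                hold_end=hold_end,
                reward=hold_end,
                outcome="correct",
            )
        )
        t = hold_end + gen.intertrial_ms
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def trial_epochs(trial: pd.Series) -> list[tuple[str, float, float]]:
    """Epoch name and [start, end) bounds tiling one trial, in ms.

    The memory period is split into its first 500 ms (early memory) and the
    remainder (late memory); the movement epoch spans go cue to object lift.
    """
    memory_start = float(trial["memory_start"])
    go = float(trial["go"])
    early_end = min(memory_start + 500.0, go)
    return [
        ("baseline", float(trial["trial_start"]), float(trial["cue_on"])),
        ("cue", float(trial["cue_on"]), memory_start),
        ("early_memory", memory_start, early_end),
        ("late_memory", early_end, go),
        ("move", go, float(trial["object_lifted"])),
        ("hold", float(trial["object_lifted"]), float(trial["hold_end"])),
    ]
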
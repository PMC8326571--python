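"""Shared fixtures: synthetic sessions at a few sizes, generated once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import graspflow as gf


@pytest.fixture(scope="session")
def default_session() -> gf.Session:
    """Full-size session at generator defaults (14-18 trials/condition)."""
    return gf.generate_session(seed=1)


@pytest.fixture(scope="session")
def fixed15_session() -> gf.Session:
    """Session with exactly 15 trials per condition, zero modality offset."""
    cfg = gf.TaskConfig(trials_per_condition_range=(15, 15))
    return gf.generate_session(cfg=cfg, seed=11)


@pytest.fixture(scope="session")
def small_session() -> gf.Session:
    """Tiny session for fast structural checks."""
    cfg = gf.TaskConfig(trials_per_condition_range=(3, 4), n_objects=3)
    gen = gf.GeneratorSettings(unit_counts={"F5": 4, "AIP": 2})
    return gf.generate_session(cfg=cfg, gen=gen, seed=5)


@pytest.fixture(scope="session")
def broadband_session() -> gf.Session:
    """Short 16-channel session with rendered broadband signal."""
    cfg = gf.TaskConfig(trials_per_condition_range=(2, 2), n_objects=1)
    gen = gf.GeneratorSettings(
        unit_counts={"F5": 8, "M1": 8}, baseline_rate_range_hz=(5.0, 10.0)
    )
    return gf.generate_session(
        cfg=cfg, gen=gen, seed=3, continuous=True, kinematics=False
    )


def make_trial(
    trial_id: int = 0,
    obj: str = "sphere",
    modality: str = "visual",
    memory_ms: float = 1200.0,
    rt_ms: float = 259.0,
    mt_ms: float = 308.0,
    hold_ms: float = 700.0,
    start: float = 0.0,
) -> dict:
    """Hand-built correct trial with explicit timing."""
    cue_on = start + 500.0
    cue_off = cue_on + 700.0
    go = cue_off + memory_ms
    movement_onset = go + rt_ms
    lifted = movement_onset + mt_ms
    return dict(
        trial_id=trial_id,
        object=obj,
        modality=modality,
        trial_start=start,
        cue_on=cue_on,
        expl_movement_onset=np.nan,
        exploration_lift=np.nan,
        handrest_return=np.nan,
        cue_off=cue_off,
        memory_start=cue_off,
        go=go,
        movement_onset=movement_onset,
        object_lifted=lifted,
        hold_end=lifted + hold_ms,
        reward=lifted + hold_ms,
        outcome="correct",
    )


def trials_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def match_events(
    detected_ms: np.ndarray, true_ms: np.ndarray, tol_ms: float = 0.5
) -> tuple[float, float, float]:
    """Greedy event matching; returns (precision, recall, F1)."""
    used = np.zeros(len(true_ms), dtype=bool)
    tp = 0
    for t in detected_ms:
        j = np.searchsorted(true_ms, t)
        for k in (j - 1, j):
            if 0 <= k < len(true_ms) and not used[k] and abs(true_ms[k] - t) <= tol_ms:
                used[k] = True
                tp += 1
                break
    precision = tp / max(len(detected_ms), 1)
    recall = tp / max(len(true_ms), 1)
    f1 = 2 * precision * recall / max(precision + recall, 1e-12)
    return precision, recall, f1


def mean_abs_corr(x: np.ndarray) -> float:
    """Mean absolute off-diagonal cross-channel correlation."""
    c = np.corrcoef(x)
    return float(np.abs(c[np.triu_indices_from(c, 1)]).mean())
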
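"""Behavioral validation and reaction-/movement-time analysis.

Reaction time (RT) in the grasp phase is the interval from the go cue to
handrest release; movement time (MT) runs from handrest release to the
completed object lift. In the tactile exploration phase the analogous
definitions apply: RT from the cue instruction to handrest release, MT from
release to the exploration lift. Incorrect trials (epoch order violated,
premature movement, paradigm duration bounds exceeded) are excluded from
all statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import TaskConfig

#: Event order required of every correct trial (exploration events are
#: checked only when present, i.e. on tactile trials).
_ORDER = (
    "trial_start",
    "cue_on",
    "expl_movement_onset",
    "exploration_lift",
    "handrest_return",
    "cue_off",
    "memory_start",
    "go",
    "movement_onset",
    "object_lifted",
    "hold_end",
)

_REQUIRED = (
    "trial_start",
    "cue_on",
    "cue_off",
    "memory_start",
    "go",
    "movement_onset",
    "object_lifted",
    "hold_end",
)


@dataclass
class TimingSummary:
    """Histogram and mean of one timing measure for one trial subset.

    The histogram covers [0, cutoff) at the given bin width; values beyond
    the cutoff are dropped from the histogram but kept in the mean (the
    cutoff is a display convention, not a data filter).
    """

    phase: str
    metric: str
    modality: str | None
    n: int
    mean_ms: float
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_beyond_cutoff(self) -> int:
        return self.n - int(self.counts.sum())


def _classify(trial: Mapping, cfg: TaskConfig, tol: float = 1e-9) -> str:
    for name in _REQUIRED:
        v = trial.get(name) if hasattr(trial, "get") else trial[name]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return f"error:missing-event:{name}"
    if trial["movement_onset"] < trial["go"]:
        return "error:premature"
    present = [
        (name, float(trial[name]))
        for name in _ORDER
        if name in trial and not pd.isna(trial[name])
    ]
    times = [t for _, t in present]
    if any(b < a - tol for a, b in zip(times, times[1:])):
        return "error:order"
    memory = float(trial["go"]) - float(trial["memory_start"])
    lo, hi = cfg.memory_ms_range
    if not (lo - tol <= memory <= hi + tol):
        return "error:paradigm-violation"
    if float(trial["movement_onset"]) - float(trial["go"]) > cfg.go_window_ms + tol:
        return "error:late"
    return "correct"


def validate_trials(events: pd.DataFrame, cfg: TaskConfig) -> pd.DataFrame:
    """Classify each trial as correct or a named error.

    Trials failing the paradigm's epoch order or duration bounds get an
    ``error:<reason>`` outcome and are excluded by every downstream
    statistic. Rows without a trial id are skipped with a warning. The
    check is deterministic and row-order independent.
    """
    if "trial_id" not in events.columns:
        raise ValueError("events table needs a trial_id column")
    orphans = events["trial_id"].isna()
    if orphans.any():
        warnings.warn(f"skipping {int(orphans.sum())} events without a trial id")
        events = events[~orphans]
    out = events.copy()
    out["outcome"] = [
        _classify(row, cfg) for row in events.to_dict(orient="records")
    ]
    return out


def reaction_time(trial: Mapping, phase: str = "grasp") -> float:
    """RT of one correct trial: go (or cue) to handrest release, >= 0."""
    if phase == "grasp":
        rt = float(trial["movement_onset"]) - float(trial["go"])
    elif phase == "exploration":
        rt = float(trial["expl_movement_onset"]) - float(trial["cue_on"])
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if np.isnan(rt) or rt < 0:
        raise ValueError(f"invalid {phase} reaction time {rt}")
    return rt


def movement_time(trial: Mapping, phase: str = "grasp") -> float:
    """MT of one correct trial: handrest release to completed lift, >= 0."""
    if phase == "grasp":
        mt = float(trial["object_lifted"]) - float(trial["movement_onset"])
    elif phase == "exploration":
        mt = float(trial["exploration_lift"]) - float(trial["expl_movement_onset"])
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if np.isnan(mt) or mt < 0:
        raise ValueError(f"invalid {phase} movement time {mt}")
    return mt


def _phase_values(
    trials: pd.DataFrame, phase: str, metric: str, modality: str | None
) -> np.ndarray:
    sel = trials[trials["outcome"] == "correct"]
    if phase == "exploration":
        sel = sel[sel["modality"] == "tactile"]
    elif modality is not None:
        sel = sel[sel["modality"] == modality]
    func = reaction_time if metric == "reaction" else movement_time
    return np.array([func(row, phase) for row in sel.to_dict(orient="records")])


def timing_summary(
    trials: pd.DataFrame,
    phase: str,
    metric: str = "reaction",
    bin_ms: float = 5.0,
    cutoff_ms: float = 550.0,
    modality: str | None = None,
) -> TimingSummary:
    """Histogram and mean of RT or MT over the correct trials of a phase.

    ``metric`` is ``"reaction"`` or ``"movement"``. Defaults match the
    standard display conventions (RT: 5 ms bins cut at 550 ms; MT is
    typically shown with 10 ms bins cut at 1,000 ms).
    """
    if metric not in ("reaction", "movement"):
        raise ValueError("metric must be 'reaction' or 'movement'")
    values = _phase_values(trials, phase, metric, modality)
    edges = np.arange(0.0, cutoff_ms + bin_ms / 2, bin_ms)
    if values.size == 0:
        warnings.warn(f"no correct trials for phase={phase!r}, modality={modality!r}")
        return TimingSummary(
            phase=phase,
            metric=metric,
            modality=modality,
            n=0,
            mean_ms=float("nan"),
            bin_edges=edges,
            counts=np.zeros(len(edges) - 1, dtype=int),
        )
    counts, _ = np.histogram(values[values < cutoff_ms], bins=edges)
    return TimingSummary(
        phase=phase,
        metric=metric,
        modality=modality,
        n=int(values.size),
        mean_ms=float(values.mean()),
        bin_edges=edges,
        counts=counts,
    )


def timing_table(
    trials: pd.DataFrame | Iterable[pd.DataFrame],
) -> pd.DataFrame:
    """RT/MT means per phase and modality (sessions pooled by concatenation)."""
    if not isinstance(trials, pd.DataFrame):
        trials = pd.concat(list(trials), ignore_index=True)
    rows = []
    for phase, metric, modality in (
        ("exploration", "reaction", None),
        ("exploration", "movement", None),
        ("grasp", "reaction", "visual"),
        ("grasp", "reaction", "tactile"),
        ("grasp", "movement", "visual"),
        ("grasp", "movement", "tactile"),
    ):
        values = _phase_values(trials, phase, metric, modality)
        rows.append(
            dict(
                phase=phase,
                metric=metric,
                modality=modality or "tactile",
                n=int(values.size),
                mean_ms=float(values.mean()) if values.size else float("nan"),
            )
        )
    return pd.DataFrame(rows)
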
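"""Shared in-memory containers for sessions, spikes, kinematics and signals.

Trials are carried as a pandas DataFrame with one row per trial and one
column per named event timestamp (milliseconds from session start); this is
the canonical on-disk layout of ``events.csv`` as well. Spike trains are
per-unit sorted time arrays; kinematics are per-trial time/joint-angle
traces; broadband data is a channels-by-samples matrix in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Event columns of the trials table, in paradigm order. Exploration events
#: are only populated for tactile trials (NaN otherwise).
EVENT_COLUMNS: tuple[str, ...] = (
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
    "reward",
)

TRIAL_COLUMNS: tuple[str, ...] = ("trial_id", "object", "modality") + EVENT_COLUMNS + (
    "outcome",
)


@dataclass
class SpikeData:
    """Sorted spike trains for a population of units.

    Parameters
    ----------
    units:
        One row per unit with columns ``unit_id``, ``area``, ``n_spikes``,
        ``mean_rate_hz`` and ``qc_pass``.
    trains:
        Mapping of unit_id to a strictly increasing array of spike times in
        milliseconds from session start.
    duration_ms:
        Length of the recording the rates refer to.
    """

    units: pd.DataFrame
    trains: dict[str, np.ndarray]
    duration_ms: float

    def __post_init__(self) -> None:
        for uid, t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if t.ndim != 1:
                raise ValueError(f"spike train {uid} must be 1-D")
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError(f"spike train {uid} must be sorted")
            self.trains[uid] = t

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units["unit_id"])

    def passing(self) -> "SpikeData":
        """Restrict to units whose quality-control flag is set."""
        keep = self.units[self.units["qc_pass"]].reset_index(drop=True)
        trains = {u: self.trains[u] for u in keep["unit_id"]}
        return SpikeData(units=keep, trains=trains, duration_ms=self.duration_ms)

    def area_of(self, unit_id: str) -> str:
        row = self.units.loc[self.units["unit_id"] == unit_id, "area"]
        return str(row.iloc[0])


@dataclass
class KinematicTrace:
    """Joint-angle trace for one trial: times in ms, angles in degrees."""

    trial_id: int
    times: np.ndarray  # (T,)
    angles: np.ndarray  # (T, D)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.ndim != 1 or self.angles.ndim != 2:
            raise ValueError("times must be 1-D and angles 2-D")
        if self.times.shape[0] != self.angles.shape[0]:
            raise ValueError("times and angles must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_dims(self) -> int:
        return self.angles.shape[1]


@dataclass
class ContinuousRecording:
    """Multichannel broadband signal in microvolts.

    ``truth`` optionally carries simulation ground truth: per-channel spike
    sample indices (``spike_samples``) and the injected common-mode artifact
    matrix (``artifact``, channels x samples), used to score preprocessing.
    """

    samples: np.ndarray  # (channels, time), microvolts
    rate_hz: float
    channel_meta: pd.DataFrame  # channel, area, noise_flag
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.rate_hz * 1000.0


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover.

    Untuned units have all tuning gains exactly zero; tuned units carry one
    gain per trial epoch. ``object_pref`` holds each unit's per-object
    tuning score in [-1, 1].
    """

    master_seed: int
    unit_table: pd.DataFrame  # unit_id, area, baseline_hz, object_tuned, modality_tuned
    object_gain: np.ndarray  # (n_units, n_epochs)
    modality_gain: np.ndarray  # (n_units, n_epochs)
    object_pref: np.ndarray  # (n_units, n_objects)
    epoch_rate_gain: dict[str, float]
    canonical_postures: np.ndarray  # (n_objects, D)
    modality_offset: np.ndarray  # (D,) added to tactile-trial postures
    rest_posture: np.ndarray  # (D,)
    timing: dict[str, Any]
    artifact: dict[str, Any] | None = None


@dataclass
class Session:
    """One complete (synthetic or loaded) recording session."""

    trials: pd.DataFrame
    spikes: SpikeData | None = None
    kinematics: list[KinematicTrace] = field(default_factory=list)
    continuous: ContinuousRecording | None = None
    ground_truth: GroundTruth | None = None
    config: Any = None
    generator: Any = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_ms(self) -> float:
        if self.spikes is not None:
            return self.spikes.duration_ms
        return float(self.trials["hold_end"].max())

    def correct_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["outcome"] == "correct"].reset_index(drop=True)
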
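"""Inhomogeneous-Poisson spike-train simulation.

Each unit's rate is piecewise constant over trial epochs:

    lambda_u(t) = beta_u * g_epoch(t) * (1 + a_u(e) * f_obj + b_u(e) * f_mod)

clipped at zero, where ``beta_u`` is the unit's baseline rate, ``g_epoch``
the shared per-epoch excitability, ``a_u``/``b_u`` the unit's object and
modality gains in the current epoch (exactly zero for untuned units),
``f_obj`` the unit's tuning score for the trial's object and ``f_mod`` is
+1 for visual and -1 for tactile trials. Outside trials the rate is the
baseline rate. Spikes are drawn by thinning a homogeneous Poisson process
at the unit's maximum rate; each unit has its own random stream so the
population is extensible without perturbing existing trains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import EPOCHS, ConfigError, GeneratorSettings, TaskConfig
from ..types import GroundTruth, SpikeData
from ._rng import unit_stream
from .schedule import trial_epochs

_EPOCH_INDEX = {name: i for i, name in enumerate(EPOCHS)}


def build_rate_segments(
    trials: pd.DataFrame, cfg: TaskConfig, duration_ms: float
) -> dict[str, np.ndarray]:
    """Tile the recording [0, duration) into constant-rate segments.

    Returns arrays ``start``, ``end``, ``epoch`` (index into EPOCHS),
    ``obj`` (object index, -1 between trials) and ``mod`` (+1 visual,
    -1 tactile, 0 between trials).
    """
    objects = list(cfg.objects)
    starts: list[float] = []
    ends: list[float] = []
    epochs: list[int] = []
    objs: list[int] = []
    mods: list[int] = []

    def add(s: float, e: float, epoch: int, obj: int, mod: int) -> None:
        if e > s:
            starts.append(s)
            ends.append(e)
            epochs.append(epoch)
            objs.append(obj)
            mods.append(mod)

    t_prev = 0.0
    for _, trial in trials.sort_values("trial_start").iterrows():
        add(t_prev, float(trial["trial_start"]), _EPOCH_INDEX["baseline"], -1, 0)
        obj = objects.index(trial["object"])
        mod = 1 if trial["modality"] == "visual" else -1
        for name, s, e in trial_epochs(trial):
            add(s, e, _EPOCH_INDEX[name], obj, mod)
        t_prev = float(trial["hold_end"])
    add(t_prev, duration_ms, _EPOCH_INDEX["baseline"], -1, 0)
    return {
        "start": np.array(starts),
        "end": np.array(ends),
        "epoch": np.array(epochs, dtype=int),
        "obj": np.array(objs, dtype=int),
        "mod": np.array(mods, dtype=int),
    }


def _unit_segment_rates(
    gt: GroundTruth, unit_index: int, segments: dict[str, np.ndarray]
) -> np.ndarray:
    """Firing rate (Hz) of one unit in every segment, clipped at zero."""
    beta = float(gt.unit_table["baseline_hz"].iloc[unit_index])
    if beta < 0:
        raise ConfigError(f"negative baseline rate for unit index {unit_index}")
    g = np.array([gt.epoch_rate_gain[EPOCHS[e]] for e in segments["epoch"]])
    a = gt.object_gain[unit_index, segments["epoch"]]
    b = gt.modality_gain[unit_index, segments["epoch"]]
    f_obj = np.where(
        segments["obj"] >= 0,
        gt.object_pref[unit_index, np.clip(segments["obj"], 0, None)],
        0.0,
    )
    f_mod = segments["mod"].astype(float)
    return np.clip(beta * g * (1.0 + a * f_obj + b * f_mod), 0.0, None)


def _thin_poisson(
    rng: np.random.Generator,
    rates_hz: np.ndarray,
    seg_start: np.ndarray,
    duration_ms: float,
) -> np.ndarray:
    """Draw one spike train by thinning against a piecewise-constant rate."""
    lam_max = float(rates_hz.max(initial=0.0))
    if lam_max <= 0:
        return np.empty(0)
    expected = lam_max * duration_ms / 1000.0
    n = rng.poisson(expected)
    t = np.sort(rng.uniform(0.0, duration_ms, n))
    idx = np.searchsorted(seg_start, t, side="right") - 1
    accept = rng.uniform(size=n) < rates_hz[idx] / lam_max
    return t[accept]


def simulate_spike_trains(
    trials: pd.DataFrame,
    ground_truth: GroundTruth,
    cfg: TaskConfig,
    gen: GeneratorSettings,
    seed: int,
    duration_ms: float | None = None,
) -> SpikeData:
    """Simulate the whole population's spike trains for one session."""
    if duration_ms is None:
        duration_ms = float(trials["hold_end"].max()) + gen.intertrial_ms
    segments = build_rate_segments(trials, cfg, duration_ms)
    trains: dict[str, np.ndarray] = {}
    rows = []
    for i, row in ground_truth.unit_table.iterrows():
        rates = _unit_segment_rates(ground_truth, i, segments)
        rng = unit_stream(ground_truth.master_seed if seed is None else seed, i)
        t = _thin_poisson(rng, rates, segments["start"], duration_ms)
        uid = str(row["unit_id"])
        trains[uid] = t
        rows.append(
            dict(
                unit_id=uid,
                area=row["area"],
                n_spikes=len(t),
                mean_rate_hz=len(t) / (duration_ms / 1000.0),
                qc_pass=True,
            )
        )
    units = pd.DataFrame(rows, columns=["unit_id", "area", "n_spikes", "mean_rate_hz", "qc_pass"])
    return SpikeData(units=units, trains=trains, duration_ms=duration_ms)
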
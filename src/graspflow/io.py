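"""On-disk session container.

A session is a directory of plain-text tables plus an optional flat binary
broadband file:

* ``events.csv`` — one row per trial: ids, condition, named event
  timestamps (ms), outcome.
* ``spikes.csv`` — long format: unit_id, area, spike_time_ms.
* ``kinematics.csv`` — long format: trial_id, time_ms, angle_00..angle_NN
  (degrees).
* ``config.json`` — task and generator settings.
* ``ground_truth.json`` — generator ground truth (when present).
* ``continuous.bin`` + ``continuous.json`` — int16 channels-x-samples with
  a JSON sidecar giving rate, channel count and microvolt gain.

Real recordings exported to the same layout load through the same entry
points.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import GeneratorSettings, TaskConfig
from .types import (
    ContinuousRecording,
    GroundTruth,
    KinematicTrace,
    Session,
    SpikeData,
    TRIAL_COLUMNS,
)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_session(session: Session, path: str | Path) -> Path:
    """Write a session directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(path / "events.csv", index=False)

    if session.spikes is not None:
        frames = []
        for _, row in session.spikes.units.iterrows():
            t = session.spikes.trains[row["unit_id"]]
            frames.append(
                pd.DataFrame(
                    {
                        "unit_id": row["unit_id"],
                        "area": row["area"],
                        "spike_time_ms": t,
                    }
                )
            )
        spikes_df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["unit_id", "area", "spike_time_ms"])
        )
        spikes_df.to_csv(path / "spikes.csv", index=False)
        meta = {
            "duration_ms": session.spikes.duration_ms,
            "units": session.spikes.units.to_dict(orient="records"),
        }
        (path / "spikes_meta.json").write_text(json.dumps(_jsonable(meta), indent=1))

    if session.kinematics:
        frames = []
        for trace in session.kinematics:
            df = pd.DataFrame(
                trace.angles,
                columns=[f"angle_{d:02d}" for d in range(trace.n_dims)],
            )
            df.insert(0, "time_ms", trace.times)
            df.insert(0, "trial_id", trace.trial_id)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            path / "kinematics.csv", index=False
        )

    cfg_payload = {
        "task": session.config.to_dict() if session.config else None,
        "generator": session.generator.to_dict() if session.generator else None,
    }
    (path / "config.json").write_text(json.dumps(_jsonable(cfg_payload), indent=1))

    if session.ground_truth is not None:
        gt = session.ground_truth
        payload = {
            "master_seed": gt.master_seed,
            "unit_table": gt.unit_table.to_dict(orient="records"),
            "object_gain": gt.object_gain,
            "modality_gain": gt.modality_gain,
            "object_pref": gt.object_pref,
            "epoch_rate_gain": gt.epoch_rate_gain,
            "canonical_postures": gt.canonical_postures,
            "modality_offset": gt.modality_offset,
            "rest_posture": gt.rest_posture,
            "timing": gt.timing,
            "artifact": gt.artifact,
        }
        (path / "ground_truth.json").write_text(
            json.dumps(_jsonable(payload), indent=1)
        )

    if session.continuous is not None:
        save_continuous(session.continuous, path)
    return path


def save_continuous(rec: ContinuousRecording, path: str | Path) -> None:
    """Write broadband data as int16 with a JSON sidecar (gain in µV/LSB)."""
    path = Path(path)
    peak = float(np.abs(rec.samples).max())
    gain = max(peak / 32000.0, 1e-6)
    data = np.round(rec.samples / gain).astype(np.int16)
    data.tofile(path / "continuous.bin")
    sidecar = {
        "rate_hz": rec.rate_hz,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "gain_uv_per_lsb": gain,
        "dtype": "int16",
        "order": "channels_x_samples",
        "channel_meta": rec.channel_meta.to_dict(orient="records"),
    }
    (path / "continuous.json").write_text(json.dumps(_jsonable(sidecar), indent=1))


def load_continuous(path: str | Path) -> ContinuousRecording:
    path = Path(path)
    sidecar = json.loads((path / "continuous.json").read_text())
    data = np.fromfile(path / "continuous.bin", dtype=np.int16)
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"])
    return ContinuousRecording(
        samples=data.astype(float) * sidecar["gain_uv_per_lsb"],
        rate_hz=sidecar["rate_hz"],
        channel_meta=pd.DataFrame(sidecar["channel_meta"]),
    )


def load_session(path: str | Path, continuous: bool = False) -> Session:
    """Load a session directory written by :func:`save_session`."""
    path = Path(path)
    trials = pd.read_csv(path / "events.csv")
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            trials[col] = np.nan

    cfg = gen = None
    cfg_file = path / "config.json"
    if cfg_file.exists():
        payload = json.loads(cfg_file.read_text())
        if payload.get("task"):
            task = dict(payload["task"])
            for key in (
                "memory_ms_range",
                "trials_per_condition_range",
                "glove_rate_hz_range",
                "modalities",
            ):
                if key in task and isinstance(task[key], list):
                    task[key] = tuple(task[key])
            cfg = TaskConfig(**task)
        if payload.get("generator"):
            g = dict(payload["generator"])
            for key in ("baseline_rate_range_hz", "canonical_range_deg"):
                if key in g and isinstance(g[key], list):
                    g[key] = tuple(g[key])
            gen = GeneratorSettings(**g)

    spikes = None
    spikes_file = path / "spikes.csv"
    if spikes_file.exists():
        df = pd.read_csv(spikes_file)
        meta_file = path / "spikes_meta.json"
        if meta_file.exists():
            meta = json.loads(meta_file.read_text())
            units = pd.DataFrame(meta["units"])
            duration = float(meta["duration_ms"])
        else:
            units = (
                df.groupby(["unit_id", "area"], sort=True)
                .size()
                .rename("n_spikes")
                .reset_index()
            )
            duration = float(df["spike_time_ms"].max()) if len(df) else 0.0
            units["mean_rate_hz"] = units["n_spikes"] / max(duration / 1000.0, 1e-9)
            units["qc_pass"] = True
        trains = {
            uid: np.sort(df.loc[df["unit_id"] == uid, "spike_time_ms"].to_numpy())
            for uid in units["unit_id"]
        }
        spikes = SpikeData(units=units, trains=trains, duration_ms=duration)

    traces: list[KinematicTrace] = []
    kin_file = path / "kinematics.csv"
    if kin_file.exists():
        kin = pd.read_csv(kin_file)
        angle_cols = sorted(c for c in kin.columns if c.startswith("angle_"))
        for trial_id, group in kin.groupby("trial_id", sort=True):
            traces.append(
                KinematicTrace(
                    trial_id=int(trial_id),
                    times=group["time_ms"].to_numpy(),
                    angles=group[angle_cols].to_numpy(),
                )
            )

    ground_truth = None
    gt_file = path / "ground_truth.json"
    if gt_file.exists():
        g = json.loads(gt_file.read_text())
        ground_truth = GroundTruth(
            master_seed=g["master_seed"],
            unit_table=pd.DataFrame(g["unit_table"]),
            object_gain=np.asarray(g["object_gain"]),
            modality_gain=np.asarray(g["modality_gain"]),
            object_pref=np.asarray(g["object_pref"]),
            epoch_rate_gain=g["epoch_rate_gain"],
            canonical_postures=np.asarray(g["canonical_postures"]),
            modality_offset=np.asarray(g["modality_offset"]),
            rest_posture=np.asarray(g["rest_posture"]),
            timing=g["timing"],
            artifact=g.get("artifact"),
        )

    rec = None
    if continuous and (path / "continuous.json").exists():
        rec = load_continuous(path)

    return Session(
        trials=trials,
        spikes=spikes,
        kinematics=traces,
        continuous=rec,
        ground_truth=ground_truth,
        config=cfg,
        generator=gen,
    )
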
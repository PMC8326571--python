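"""Broadband-to-spike-train preprocessing.

The pipeline mirrors standard extracellular practice for floating-array
recordings sampled at 30 kS/s:

1. ``median_subtract`` — running-median high-pass: the slow component is
   estimated with a ~3.33 ms median filter and subtracted, leaving the
   spike band.
2. ``lowpass`` — 4th-order Butterworth at 5 kHz, applied forward-backward
   (zero phase), so spike trough times are not displaced.
3. ``pca_artifact_cancel`` — channels are normalized to unit variance and
   decomposed with PCA; components loading broadly across channels
   (|loading| above a threshold on at least half of the channels) are
   treated as common-mode artifact and projected out.
4. ``detect_spikes`` — negative threshold crossings at a multiple of the
   robust noise estimate ``median(|x|)/0.6745`` with a 1 ms lockout.
5. ``qc_units`` — units below a minimum mean firing rate (1 Hz) are
   excluded from all downstream analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, asdict
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .types import ContinuousRecording, SpikeData


@dataclass(frozen=True)
class PreprocessParams:
    """Defaults of the preprocessing stack (all units as named)."""

    median_window_ms: float = 3.33
    butter_order: int = 4
    butter_cutoff_hz: float = 5000.0
    pca_coef_threshold: float = 0.36
    pca_channel_fraction: float = 0.5
    detect_threshold_sd: float = 4.5
    refractory_ms: float = 1.0
    min_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def median_window_samples(window_ms: float, rate_hz: float) -> int:
    """Median window length in samples, forced odd (a running median needs
    a center sample); 3.33 ms at 30 kS/s gives 100 and is rounded to 101."""
    n = int(round(window_ms * rate_hz / 1000.0))
    if n % 2 == 0:
        n += 1
    return n


def median_subtract(
    rec: ContinuousRecording, window_ms: float = 3.33
) -> ContinuousRecording:
    """Subtract the running median from every channel.

    Constant segments map to zero; an isolated impulse much shorter than
    the window is preserved unchanged.
    """
    n = median_window_samples(window_ms, rec.rate_hz)
    if n < 3:
        raise ValueError("median window must span at least 3 samples")
    if n > rec.n_samples:
        raise ValueError("median window longer than the recording")
    baseline = ndimage.median_filter(rec.samples, size=(1, n), mode="nearest")
    return replace(rec, samples=rec.samples - baseline)


def lowpass(
    rec: ContinuousRecording, order: int = 4, cutoff_hz: float = 5000.0
) -> ContinuousRecording:
    """Zero-phase (forward-backward) Butterworth low-pass filtering."""
    nyquist = rec.rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def pca_artifact_cancel(
    rec: ContinuousRecording,
    coef_threshold: float = 0.36,
    channel_fraction: float = 0.5,
    flagged_are_artifact: bool = True,
    loading_scale: str = "correlation",
) -> tuple[ContinuousRecording, dict[str, Any]]:
    """Remove common-mode components shared across channels.

    Channels are mean-centered and scaled to unit variance, then decomposed
    into principal components over channel space. A component counts as
    common-mode artifact when at least ``channel_fraction`` of channels
    have a loading magnitude above ``coef_threshold`` — a genuinely shared
    component loads broadly, whereas channel-specific activity concentrates
    its loading on few channels. Flagged components are projected out of
    the normalized data and the signal is rescaled back.

    With the default ``loading_scale="correlation"`` the coefficient tested
    against the threshold is the correlation between the component score
    and the normalized channel (eigenvector entry times the square root of
    the eigenvalue), which makes the 0.36 threshold independent of channel
    count: a strong common-mode component correlates highly with most
    channels regardless of array size, while noise components do not.
    ``loading_scale="unit"`` tests the raw unit-norm eigenvector entries
    instead.

    ``flagged_are_artifact=False`` flips the reading: flagged components
    are kept and everything else removed.

    Returns the cleaned recording and a report with the removed component
    indices, their loadings, and the fraction of variance removed.
    """
    if rec.n_channels < 2:
        raise ValueError("artifact cancellation requires at least 2 channels")
    if loading_scale not in ("correlation", "unit"):
        raise ValueError(f"unknown loading_scale {loading_scale!r}")
    x = rec.samples
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / sd

    cov = z @ z.T / z.shape[1]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if loading_scale == "correlation":
        coefs = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))[None, :]
    else:
        coefs = eigvecs
    broad = (np.abs(coefs) > coef_threshold).mean(axis=0) >= channel_fraction
    remove = broad if flagged_are_artifact else ~broad
    removed_idx = np.flatnonzero(remove)

    if removed_idx.size:
        basis = eigvecs[:, removed_idx]
        z_clean = z - basis @ (basis.T @ z)
    else:
        z_clean = z
    cleaned = z_clean * sd + mean

    total = eigvals.sum()
    report = {
        "removed_components": removed_idx.tolist(),
        "n_removed": int(removed_idx.size),
        "variance_removed": float(eigvals[removed_idx].sum() / total)
        if total > 0
        else 0.0,
        "loadings": eigvecs[:, removed_idx],
        "eigenvalues": eigvals,
        "coef_threshold": coef_threshold,
        "channel_fraction": channel_fraction,
    }
    return replace(rec, samples=cleaned), report


def robust_sd(x: np.ndarray) -> float:
    """Noise standard deviation estimate: median(|x|)/0.6745."""
    return float(np.median(np.abs(x)) / 0.6745)


def detect_spikes(
    rec: ContinuousRecording,
    threshold_sd: float = 4.5,
    refractory_ms: float = 1.0,
) -> dict[int, np.ndarray]:
    """Detect negative threshold crossings per channel.

    The signal must already be spike-band filtered. Events are troughs
    exceeding ``threshold_sd`` times the robust noise estimate, with a
    refractory lockout so crossings closer than ``refractory_ms`` collapse
    into a single event. Event times (ms) are trough samples.
    """
    lockout = max(int(round(refractory_ms / 1000.0 * rec.rate_hz)), 1)
    events: dict[int, np.ndarray] = {}
    for c in range(rec.n_channels):
        x = rec.samples[c]
        thr = threshold_sd * robust_sd(x)
        if thr <= 0:
            events[c] = np.empty(0)
            continue
        peaks, _ = signal.find_peaks(-x, height=thr, distance=lockout)
        events[c] = peaks / rec.rate_hz * 1000.0
    return events


def spikes_from_detection(
    events: dict[int, np.ndarray],
    rec: ContinuousRecording,
) -> SpikeData:
    """Wrap per-channel detections as units (1:1 channel-to-unit mapping).

    Waveform sorting is outside this pipeline; in simulation mode each
    channel carries a single ground-truth unit, so the mapping is exact.
    """
    rows = []
    trains: dict[str, np.ndarray] = {}
    duration_ms = rec.duration_ms
    meta = rec.channel_meta.set_index("channel")
    for c, t in events.items():
        uid = (
            str(meta.loc[c, "unit_id"])
            if "unit_id" in meta.columns
            else f"ch{c:03d}"
        )
        area = str(meta.loc[c, "area"]) if "area" in meta.columns else "unknown"
        trains[uid] = np.asarray(t, dtype=float)
        rows.append(
            dict(
                unit_id=uid,
                area=area,
                n_spikes=len(t),
                mean_rate_hz=len(t) / (duration_ms / 1000.0),
                qc_pass=True,
            )
        )
    units = pd.DataFrame(rows, columns=["unit_id", "area", "n_spikes", "mean_rate_hz", "qc_pass"])
    return SpikeData(units=units, trains=trains, duration_ms=duration_ms)


def qc_units(
    spikes: SpikeData,
    min_rate_hz: float = 1.0,
    duration_ms: float | None = None,
) -> SpikeData:
    """Flag units whose mean rate over the recording is below threshold.

    The boundary is inclusive: a unit at exactly ``min_rate_hz`` passes.
    Idempotent — re-applying with the same threshold changes nothing.
    """
    if duration_ms is None:
        duration_ms = spikes.duration_ms
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    units = spikes.units.copy()
    rates = np.array(
        [len(spikes.trains[u]) / (duration_ms / 1000.0) for u in units["unit_id"]]
    )
    units["mean_rate_hz"] = rates
    units["qc_pass"] = rates >= min_rate_hz
    return SpikeData(units=units, trains=dict(spikes.trains), duration_ms=duration_ms)


def qc_report(spikes: SpikeData) -> dict[str, Any]:
    """Per-area unit counts and per-unit rates after quality control."""
    units = spikes.units
    per_area = (
        units[units["qc_pass"]].groupby("area")["unit_id"].count().to_dict()
    )
    return {
        "n_units_total": int(len(units)),
        "n_units_passing": int(units["qc_pass"].sum()),
        "units_per_area": {str(k): int(v) for k, v in per_area.items()},
        "units": units.to_dict(orient="records"),
    }


def preprocess_recording(
    rec: ContinuousRecording, params: PreprocessParams | None = None
) -> tuple[SpikeData, dict[str, Any]]:
    """Run the full stack: median high-pass, low-pass, artifact
    cancellation, detection, unit QC. Returns spikes and a report."""
    params = params or PreprocessParams()
    banded = median_subtract(rec, params.median_window_ms)
    banded = lowpass(banded, params.butter_order, params.butter_cutoff_hz)
    cleaned, pca_rep = pca_artifact_cancel(
        banded, params.pca_coef_threshold, params.pca_channel_fraction
    )
    events = detect_spikes(cleaned, params.detect_threshold_sd, params.refractory_ms)
    spikes = spikes_from_detection(events, rec)
    spikes = qc_units(spikes, params.min_rate_hz)
    report = {"pca": pca_rep, "qc": qc_report(spikes), "params": params.to_dict()}
    return spikes, report
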
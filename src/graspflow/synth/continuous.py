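"""Broadband multichannel signal synthesis for preprocessing validation.

Each unit is assigned to its own channel (one unit per channel, matching
the pipeline's simulation-mode 1:1 detection-to-unit mapping). A channel's
signal is the sum of

* a spike component: a biphasic extracellular template placed at every
  ground-truth spike time,
* channel noise: an equal mix of white and 1/f-shaped noise normalized to
  the configured standard deviation, independent across channels,
* a common-mode artifact: slow sinusoidal drift plus sparse broadband
  bursts, identical across channels up to a per-channel gain.

Ground-truth spike sample indices and the injected artifact matrix are
stored on the recording so preprocessing can be scored against them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import GeneratorSettings, TaskConfig
from ..types import ContinuousRecording, SpikeData
from ._rng import CONTINUOUS_STREAM, stream


def spike_template(rate_hz: float, amp_uv: float) -> np.ndarray:
    """Biphasic (negative-leading) extracellular spike template, ~1.6 ms."""
    n = max(int(round(1.6e-3 * rate_hz)), 8)
    t = np.arange(n)
    trough = n * 0.25
    rebound = n * 0.45
    w = -np.exp(-0.5 * ((t - trough) / (n * 0.06)) ** 2)
    w += 0.30 * np.exp(-0.5 * ((t - rebound) / (n * 0.12)) ** 2)
    w /= np.abs(w).max()
    return amp_uv * w


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance noise with 1/f amplitude spectrum."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f / f[-1])
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _common_artifact(
    rng: np.random.Generator, n: int, rate_hz: float, gen: GeneratorSettings
) -> np.ndarray:
    """Shared artifact waveform: slow drift plus broadband bursts."""
    t = np.arange(n) / rate_hz
    drift = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.5, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        drift += np.sin(2 * np.pi * f * t + phase)
    peak = np.abs(drift).max()
    if peak > 0:
        drift *= gen.drift_amp_uv / peak
    bursts = np.zeros(n)
    duration_s = n / rate_hz
    n_bursts = rng.poisson(gen.burst_rate_hz * duration_s)
    for _ in range(n_bursts):
        width = int(rng.uniform(5e-3, 15e-3) * rate_hz)
        start = int(rng.uniform(0, max(n - width, 1)))
        shape = rng.normal(size=width) * np.hanning(width)
        bursts[start : start + width] += gen.burst_amp_uv * shape
    shared = np.zeros(n)
    if gen.common_noise_sd_uv > 0:
        shared = gen.common_noise_sd_uv * rng.normal(size=n)
    return drift + bursts + shared


def simulate_continuous(
    spikes: SpikeData,
    cfg: TaskConfig,
    gen: GeneratorSettings,
    seed: int,
    rate_hz: float | None = None,
) -> ContinuousRecording:
    """Render spike trains into a broadband recording with noise and artifact."""
    if rate_hz is None:
        rate_hz = cfg.continuous_rate_hz
    elif rate_hz != cfg.continuous_rate_hz:
        raise ValueError(
            f"sampling rate {rate_hz} does not match configured "
            f"{cfg.continuous_rate_hz}"
        )
    rng = stream(seed, CONTINUOUS_STREAM)
    n_samples = int(np.ceil(spikes.duration_ms / 1000.0 * rate_hz))
    unit_ids = spikes.unit_ids
    n_ch = len(unit_ids)
    template = spike_template(rate_hz, gen.spike_amp_uv)
    tlen = len(template)

    trough_offset = int(np.argmin(template))  # spike time marks the trough
    signal = np.zeros((n_ch, n_samples))
    spike_samples: dict[int, np.ndarray] = {}
    for c, uid in enumerate(unit_ids):
        idx = np.round(spikes.trains[uid] / 1000.0 * rate_hz).astype(int)
        idx = idx[(idx >= trough_offset) & (idx < n_samples - tlen)]
        spike_samples[c] = idx
        for i in idx:
            start = i - trough_offset
            signal[c, start : start + tlen] += template

    if gen.noise_sd_uv > 0:
        for c in range(n_ch):
            mix = rng.normal(size=n_samples) + _pink_noise(rng, n_samples)
            sd = mix.std()
            if sd > 0:
                mix *= gen.noise_sd_uv / sd
            signal[c] += mix

    artifact = np.zeros((n_ch, n_samples))
    if gen.artifact_gain > 0 and (
        gen.drift_amp_uv > 0 or gen.burst_amp_uv > 0 or gen.common_noise_sd_uv > 0
    ):
        common = _common_artifact(rng, n_samples, rate_hz, gen)
        gains = gen.artifact_gain * rng.uniform(0.7, 1.3, n_ch)
        artifact = np.outer(gains, common)
        signal += artifact

    meta = pd.DataFrame(
        {
            "channel": np.arange(n_ch),
            "unit_id": unit_ids,
            "area": [spikes.area_of(u) for u in unit_ids],
            "noise_flag": False,
        }
    )
    return ContinuousRecording(
        samples=signal,
        rate_hz=float(rate_hz),
        channel_meta=meta,
        truth={
            "spike_samples": spike_samples,
            "artifact": artifact,
            "template": template,
        },
    )
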
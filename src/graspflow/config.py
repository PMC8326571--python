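"""Task and generator configuration for the delayed-grasping paradigm.

The paradigm models one trial of a delayed visually- or tactually-instructed
grasp: the subject sits in the dark through a baseline period, is then shown
the target object (visual trials: the object is briefly illuminated) or
explores it by hand in the dark (tactile trials), memorizes it through a
randomized delay, and on the go cue grasps and lifts the object within a
short response window, holding it until reward.

``TaskConfig`` holds the paradigm timing constants; ``GeneratorSettings``
holds everything the synthetic-session generator needs beyond the paradigm:
unit counts per cortical area, tuning structure, posture geometry, behavioral
timing distributions, and broadband-signal parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

OBJECTS: tuple[str, ...] = ("sphere", "ring", "bar", "cube", "blockring", "box")
MODALITIES: tuple[str, ...] = ("visual", "tactile")
AREAS: tuple[str, ...] = ("F5", "AIP", "M1", "S1")

#: Trial epochs used by the rate model, in paradigm order.
EPOCHS: tuple[str, ...] = (
    "baseline",
    "cue",
    "early_memory",
    "late_memory",
    "move",
    "hold",
)


class ConfigError(ValueError):
    """Raised for invalid task or generator configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing and size constants of the delayed-grasping paradigm.

    All durations are in milliseconds. Defaults reproduce the paradigm used
    in the experiment this pipeline models: 6 objects x 2 sensory modalities,
    500 ms baseline, 700 ms visual cue or up to 3,000 ms tactile exploration,
    a 1,000-1,500 ms randomized memory period, an 870 ms response window and
    a 700 ms object hold.
    """

    n_objects: int = 6
    modalities: tuple[str, ...] = MODALITIES
    baseline_ms: float = 500.0
    visual_cue_ms: float = 700.0
    tactile_cue_max_ms: float = 3000.0
    memory_ms_range: tuple[float, float] = (1000.0, 1500.0)
    go_window_ms: float = 870.0
    hold_ms: float = 700.0
    trials_per_condition_range: tuple[int, int] = (14, 18)
    continuous_rate_hz: float = 30000.0
    glove_rate_hz_range: tuple[float, float] = (70.0, 100.0)

    def __post_init__(self) -> None:
        durations = (
            self.baseline_ms,
            self.visual_cue_ms,
            self.tactile_cue_max_ms,
            self.go_window_ms,
            self.hold_ms,
            self.continuous_rate_hz,
        )
        if any(d <= 0 for d in durations):
            raise ConfigError("all durations and rates must be positive")
        lo, hi = self.memory_ms_range
        if not (0 < lo <= hi):
            raise ConfigError("memory_ms_range must satisfy 0 < lo <= hi")
        tlo, thi = self.trials_per_condition_range
        if not (0 < tlo <= thi):
            raise ConfigError("trials_per_condition_range must satisfy 0 < lo <= hi")
        glo, ghi = self.glove_rate_hz_range
        if not (0 < glo <= ghi):
            raise ConfigError("glove_rate_hz_range must satisfy 0 < lo <= hi")
        if self.n_objects <= 0:
            raise ConfigError("n_objects must be positive")

    @property
    def objects(self) -> tuple[str, ...]:
        return OBJECTS[: self.n_objects]

    @property
    def n_conditions(self) -> int:
        return self.n_objects * len(self.modalities)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _default_unit_counts() -> dict[str, int]:
    # Session-typical unit counts per area (means of the recorded sessions).
    return {"F5": 26, "AIP": 9, "M1": 65, "S1": 50}


def _default_object_profile() -> dict[str, float]:
    # Object tuning concentrated in cue and movement, some delay activity.
    return {
        "baseline": 0.0,
        "cue": 0.8,
        "early_memory": 0.35,
        "late_memory": 0.45,
        "move": 1.0,
        "hold": 0.6,
    }


def _default_modality_profile() -> dict[str, float]:
    # Modality tuning strong in cue/early memory, decaying toward movement.
    return {
        "baseline": 0.0,
        "cue": 1.0,
        "early_memory": 1.0,
        "late_memory": 0.25,
        "move": 0.05,
        "hold": 0.05,
    }


def _default_epoch_rate_gain() -> dict[str, float]:
    # Overall excitability per epoch (movement-related rate increase).
    return {
        "baseline": 1.0,
        "cue": 1.2,
        "early_memory": 1.0,
        "late_memory": 1.0,
        "move": 1.5,
        "hold": 1.2,
    }


@dataclass(frozen=True)
class GeneratorSettings:
    """Free parameters of the synthetic-session generator.

    Spiking
    -------
    Each unit fires as an inhomogeneous Poisson process with piecewise
    constant rate ``lambda(t) = beta * g_epoch * (1 + a_e * f_obj + b_e *
    f_mod)`` clipped at zero, where ``beta`` is the unit's baseline rate,
    ``g_epoch`` a shared per-epoch excitability gain, ``a_e``/``b_e`` the
    unit's object/modality gain in the current epoch (exactly 0 for untuned
    units) and ``f_obj`` in [-1, 1] / ``f_mod`` in {+1, -1} the condition
    scores.

    Kinematics
    ----------
    Each object has a canonical grasp posture in a ``posture_dim``-dimensional
    joint-angle space; a trial's settled posture is the canonical posture plus
    a modality offset (zero by default: grips are modality independent, as
    observed behaviorally) plus Gaussian posture noise. The hand moves from
    the rest posture to the grasp posture along a minimum-jerk trajectory
    during the movement epoch.

    Behavior
    --------
    Reaction and movement times are log-normal. Defaults are calibrated to
    the empirical means: exploration RT 323 ms / MT 757 ms; grasp RT 259 ms;
    grasp MT 308 ms (visual) / 310 ms (tactile).
    """

    # --- units & spiking ---
    unit_counts: dict[str, int] = field(default_factory=_default_unit_counts)
    baseline_rate_range_hz: tuple[float, float] = (4.0, 20.0)
    object_tuned_fraction: float = 0.4
    modality_tuned_fraction: float = 0.4
    object_gain: float = 0.8
    modality_gain: float = 0.8
    object_profile: dict[str, float] = field(default_factory=_default_object_profile)
    modality_profile: dict[str, float] = field(default_factory=_default_modality_profile)
    epoch_rate_gain: dict[str, float] = field(default_factory=_default_epoch_rate_gain)

    # --- kinematics ---
    posture_dim: int = 27
    rest_angle_deg: float = 10.0
    canonical_range_deg: tuple[float, float] = (10.0, 70.0)
    modality_offset_deg: float = 0.0
    posture_noise_deg: float = 4.0
    sensor_noise_deg: float = 1.0

    # --- behavioral timing (ms; sigma = log-scale dispersion) ---
    grasp_rt_mean_ms: float = 259.0
    grasp_rt_sigma: float = 0.25
    grasp_mt_mean_ms: dict[str, float] = field(
        default_factory=lambda: {"visual": 308.0, "tactile": 310.0}
    )
    grasp_mt_sigma: float = 0.2
    exploration_rt_mean_ms: float = 323.0
    exploration_rt_sigma: float = 0.35
    exploration_mt_mean_ms: float = 757.0
    exploration_mt_sigma: float = 0.35
    tactile_cue_ms: float = 2000.0
    exploration_return_ms: float = 200.0
    intertrial_ms: float = 1000.0

    # --- broadband signal ---
    spike_amp_uv: float = 80.0
    noise_sd_uv: float = 10.0
    artifact_gain: float = 1.0
    drift_amp_uv: float = 40.0
    burst_rate_hz: float = 0.5
    burst_amp_uv: float = 60.0
    common_noise_sd_uv: float = 8.0

    def __post_init__(self) -> None:
        for area, n in self.unit_counts.items():
            if n <= 0:
                raise ConfigError(f"unit count for {area} must be > 0, got {n}")
        lo, hi = self.baseline_rate_range_hz
        if lo < 0 or hi < lo:
            raise ConfigError("baseline_rate_range_hz must satisfy 0 <= lo <= hi")
        for frac in (self.object_tuned_fraction, self.modality_tuned_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("tuned fractions must lie in [0, 1]")
        if self.posture_dim <= 0:
            raise ConfigError("posture_dim must be positive")
        for name in (
            "grasp_rt_mean_ms",
            "exploration_rt_mean_ms",
            "exploration_mt_mean_ms",
            "tactile_cue_ms",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for prof in (self.object_profile, self.modality_profile, self.epoch_rate_gain):
            missing = set(EPOCHS) - set(prof)
            if missing:
                raise ConfigError(f"epoch profile missing entries for {sorted(missing)}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
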
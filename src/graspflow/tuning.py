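"""Sliding-window two-factor ANOVA tuning analysis.

Spike counts in 100 ms windows slid along the trial (default stride 10 ms)
are tested per unit and window with a two-way fixed-effects ANOVA — factor
object (six levels) and factor sensory modality (two levels), main effects
only. Because trial counts per condition vary (14-18), effects are assessed
by model comparison (type-II sums of squares): each factor's sum of squares
is the residual-sum-of-squares drop from adding it to the model already
containing the other factor. A unit is "tuned" at a window when the
Bonferroni-corrected p-value (family = number of windows per unit and
factor) is below alpha; the headline readout is the fraction of tuned units
per area over time.

The heavy lifting is one QR decomposition per design matrix, shared across
all units and windows, so the full population's time course is computed in
a handful of matrix products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SpikeData

FACTORS = ("object", "modality")


@dataclass
class BinnedCounts:
    """Spike counts per unit, trial and sliding window."""

    counts: np.ndarray  # (n_units, n_trials, n_windows)
    window_centers: np.ndarray  # ms relative to the alignment event
    window_ms: float
    stride_ms: float
    unit_ids: list[str]
    areas: list[str]
    trial_ids: np.ndarray
    objects: np.ndarray
    modalities: np.ndarray
    align_event: str


@dataclass
class TuningTimecourse:
    """Fraction of significantly tuned units over time for one area/factor."""

    area: str
    factor: str
    window_centers: np.ndarray
    fraction: np.ndarray  # in [0, 1]
    n_units: int
    alpha: float
    correction: str

    def peak(self) -> tuple[float, float]:
        """(window center, fraction) at the maximum of the time course."""
        i = int(np.argmax(self.fraction))
        return float(self.window_centers[i]), float(self.fraction[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area": self.area,
                "factor": self.factor,
                "window_center_ms": self.window_centers,
                "fraction": self.fraction,
                "n_units": self.n_units,
            }
        )


def bin_spikes(
    spikes: SpikeData,
    trials: pd.DataFrame,
    align_event: str = "go",
    span_ms: tuple[float, float] = (-1000.0, 1000.0),
    window_ms: float = 100.0,
    stride_ms: float = 10.0,
) -> BinnedCounts:
    """Count spikes in sliding windows aligned to a trial event.

    A window centered at c covers [c - w/2, c + w/2) relative to the
    alignment event; with stride below the window length adjacent windows
    overlap and a spike is counted in every window covering it. Windows
    reaching beyond the recorded interval are trimmed off with a log
    message.
    """
    passing = spikes.passing()
    unit_ids = passing.unit_ids
    correct = trials[trials["outcome"] == "correct"]
    if align_event not in correct.columns or correct[align_event].isna().any():
        raise ValueError(f"alignment event {align_event!r} missing from some trials")
    anchors = correct[align_event].to_numpy(dtype=float)
    centers = np.arange(span_ms[0], span_ms[1] + stride_ms / 2, stride_ms)
    half = window_ms / 2.0
    lo_abs = anchors.min() + centers - half
    hi_abs = anchors.max() + centers + half
    keep = (lo_abs >= 0) & (hi_abs <= spikes.duration_ms)
    if not keep.all():
        warnings.warn(
            f"trimmed {int((~keep).sum())} windows extending beyond the recording"
        )
        centers = centers[keep]
    counts = np.empty((len(unit_ids), len(correct), len(centers)), dtype=np.int64)
    for u, uid in enumerate(unit_ids):
        t = passing.trains[uid]
        # (n_trials, n_windows) absolute edges
        starts = anchors[:, None] + centers[None, :] - half
        counts[u] = np.searchsorted(t, starts + window_ms) - np.searchsorted(t, starts)
    return BinnedCounts(
        counts=counts,
        window_centers=centers,
        window_ms=window_ms,
        stride_ms=stride_ms,
        unit_ids=unit_ids,
        areas=[passing.area_of(u) for u in unit_ids],
        trial_ids=correct["trial_id"].to_numpy(),
        objects=correct["object"].to_numpy(),
        modalities=correct["modality"].to_numpy(),
        align_event=align_event,
    )


def _dummy_design(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = sorted(set(labels.tolist()))
    if len(levels) < 2:
        return np.empty((len(labels), 0))
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])


def _rss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n x m) against an orthonormal basis."""
    return (y**2).sum(axis=0) - ((q.T @ y) ** 2).sum(axis=0)


def two_way_anova_stats(
    counts: np.ndarray,
    objects: np.ndarray,
    modalities: np.ndarray,
    sqrt_transform: bool = False,
    interaction: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """F statistics and p-values of a two-way fixed-effects ANOVA.

    ``counts`` is (n_trials, m) — any number of unit/window columns sharing
    the same trial labels. Each factor's F statistic compares the full
    additive model against the model without that factor (type-II SS).
    Degenerate columns with zero residual variance give p = 1 when the
    factor explains nothing, else p = 0.

    ``interaction`` additionally returns the object-x-modality interaction
    term, tested against the full factorial model.
    """
    y = np.asarray(counts, dtype=float)
    if sqrt_transform:
        y = np.sqrt(y)
    n = y.shape[0]
    ones = np.ones((n, 1))
    d_obj = _dummy_design(np.asarray(objects))
    d_mod = _dummy_design(np.asarray(modalities))
    x_full = np.hstack([ones, d_obj, d_mod])
    x_no_obj = np.hstack([ones, d_mod])
    x_no_mod = np.hstack([ones, d_obj])

    def qr(x: np.ndarray) -> np.ndarray:
        q, r = np.linalg.qr(x)
        keep = np.abs(np.diag(r)) > 1e-10
        return q[:, keep]

    q_full, q_no_obj, q_no_mod = qr(x_full), qr(x_no_obj), qr(x_no_mod)
    p_full = q_full.shape[1]
    rss_full = _rss(q_full, y)
    f_out: dict[str, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    specs = [("object", q_no_obj, d_obj.shape[1]), ("modality", q_no_mod, d_mod.shape[1])]
    rss_denom, q_denom, p_denom = rss_full, q_full, p_full
    if interaction:
        inter = np.hstack(
            [
                (d_obj[:, i] * d_mod[:, j])[:, None]
                for i in range(d_obj.shape[1])
                for j in range(d_mod.shape[1])
            ]
        )
        q_inter = qr(np.hstack([x_full, inter]))
        rss_inter = _rss(q_inter, y)
        specs.append(("interaction", q_full, inter.shape[1]))
        rss_denom, q_denom, p_denom = rss_inter, q_inter, q_inter.shape[1]
    df_err = n - p_denom
    if df_err <= 0:
        raise ValueError("not enough trials for the requested model")
    eps = 1e-12
    for name, q_reduced, df_num in specs:
        if df_num == 0:  # factor has a single level: nothing to test
            out[name] = np.ones(y.shape[1])
            f_out[name] = np.zeros(y.shape[1])
            continue
        if name == "interaction":
            num = _rss(q_full, y) - rss_denom
        else:
            num = _rss(q_reduced, y) - rss_full
        num = np.clip(num, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (num / df_num) / (rss_denom / df_err)
        p = stats.f.sf(f, df_num, df_err)
        # zero residual variance: significant iff the factor moved the RSS
        degenerate = rss_denom < eps
        p = np.where(degenerate & (num < eps), 1.0, p)
        p = np.where(degenerate & (num >= eps), 0.0, p)
        out[name] = p
        f_out[name] = f
    return f_out, out


def two_way_anova_pvalues(
    counts: np.ndarray,
    objects: np.ndarray,
    modalities: np.ndarray,
    sqrt_transform: bool = False,
    interaction: bool = False,
) -> dict[str, np.ndarray]:
    """Main-effect (and optional interaction) p-values; see
    :func:`two_way_anova_stats`."""
    _, pvals = two_way_anova_stats(
        counts, objects, modalities, sqrt_transform, interaction
    )
    return pvals


def sliding_anova(
    binned: BinnedCounts,
    sqrt_transform: bool = False,
    interaction: bool = False,
    per_modality_object: bool = False,
) -> dict[str, np.ndarray]:
    """Two-way ANOVA at every window for every unit.

    Returns factor -> p-value array of shape (n_units, n_windows). With
    ``per_modality_object`` the object effect is additionally evaluated as
    a one-way ANOVA restricted to each modality's trials (keys
    ``object@visual`` and ``object@tactile``), matching displays that
    separate visual and tactile trials.
    """
    n_units, n_trials, n_windows = binned.counts.shape
    cells = pd.crosstab(binned.objects, binned.modalities)
    if (cells.to_numpy() < 2).any():
        raise ValueError("every object x modality cell needs >= 2 trials")
    y = binned.counts.transpose(1, 0, 2).reshape(n_trials, n_units * n_windows)
    flat = two_way_anova_pvalues(
        y, binned.objects, binned.modalities, sqrt_transform, interaction
    )
    out = {k: v.reshape(n_units, n_windows) for k, v in flat.items()}
    if per_modality_object:
        for mod in ("visual", "tactile"):
            mask = binned.modalities == mod
            sub = two_way_anova_pvalues(
                y[mask],
                binned.objects[mask],
                np.zeros(mask.sum(), dtype=int),  # constant second factor
                sqrt_transform,
            )
            out[f"object@{mod}"] = sub["object"].reshape(n_units, n_windows)
    return out


def tuned_fraction(
    pvals: dict[str, np.ndarray],
    binned: BinnedCounts,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[TuningTimecourse]:
    """Fraction of tuned units per area, factor and window.

    With Bonferroni correction a unit is tuned at a window iff its p-value
    is below ``alpha / n_windows`` (the family is the set of windows tested
    per unit and factor). ``correction="none"`` compares against alpha
    directly.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    n_windows = len(binned.window_centers)
    threshold = alpha / n_windows if correction == "bonferroni" else alpha
    areas = np.asarray(binned.areas)
    out: list[TuningTimecourse] = []
    for factor, p in pvals.items():
        tuned = p < threshold
        for area in dict.fromkeys(binned.areas):
            mask = areas == area
            out.append(
                TuningTimecourse(
                    area=area,
                    factor=factor,
                    window_centers=binned.window_centers.copy(),
                    fraction=tuned[mask].mean(axis=0),
                    n_units=int(mask.sum()),
                    alpha=alpha,
                    correction=correction,
                )
            )
    return out


def timecourse_table(timecourses: list[TuningTimecourse]) -> pd.DataFrame:
    """Long-format table over all areas and factors."""
    return pd.concat([tc.to_frame() for tc in timecourses], ignore_index=True)
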
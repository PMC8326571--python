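"""Settled-grasp posture features and grip-type similarity analysis.

The grip a subject settles into after lifting an object is summarized by
the mean joint-angle vector over a 100 ms window 450-550 ms after the lift
— late enough that the grasp is stable, early enough that the hand has not
begun to release (release is only permitted after 750 ms of holding).
Grip similarity across the 12 classes (object x modality) is quantified by
Euclidean distances between class-mean postures and displayed as an
agglomerative dendrogram; grip discriminability is quantified by
trial-balanced leave-one-out LDA via the decode module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .decode import ConfusionMatrix, balanced_loo, labels_for_scheme
from .types import KinematicTrace, Session

FEATURE_WINDOW_MS: tuple[float, float] = (450.0, 550.0)


def extract_grasp_feature(
    trace: KinematicTrace,
    trial: pd.Series | dict,
    window_ms: tuple[float, float] = FEATURE_WINDOW_MS,
    hold_ms: float = 700.0,
) -> np.ndarray | None:
    """Mean joint angles over the post-lift feature window.

    ``window_ms`` is relative to the object-lift event and must lie inside
    the hold period. Sampling is irregular (70-100 Hz), so the feature is
    the plain arithmetic mean of all samples whose time falls in the
    window, without interpolation. Returns None (with a warning) when fewer
    than 2 samples fall inside the window.
    """
    lo, hi = window_ms
    if hi > hold_ms:
        raise ValueError(
            f"feature window {window_ms} extends beyond the {hold_ms} ms hold period"
        )
    lift = float(trial["object_lifted"])
    rel = trace.times - lift
    mask = (rel >= lo) & (rel <= hi)
    if mask.sum() < 2:
        warnings.warn(
            f"trial {trace.trial_id}: only {int(mask.sum())} samples in the "
            "feature window; trial dropped"
        )
        return None
    return trace.angles[mask].mean(axis=0)


def extract_grasp_features(
    session: Session,
    window_ms: tuple[float, float] = FEATURE_WINDOW_MS,
) -> pd.DataFrame:
    """Per-trial grasp features for all correct trials of a session.

    Returns a table with trial_id, object, modality and one ``angle_XX``
    column per joint dimension.
    """
    trials = session.correct_trials().set_index("trial_id")
    hold_ms = float(session.config.hold_ms) if session.config else 700.0
    rows = []
    for trace in session.kinematics:
        if trace.trial_id not in trials.index:
            continue
        trial = trials.loc[trace.trial_id]
        posture = extract_grasp_feature(trace, trial, window_ms, hold_ms)
        if posture is None:
            continue
        row = {
            "trial_id": trace.trial_id,
            "object": trial["object"],
            "modality": trial["modality"],
        }
        row.update({f"angle_{d:02d}": posture[d] for d in range(len(posture))})
        rows.append(row)
    return pd.DataFrame(rows)


def _angle_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c.startswith("angle_")]


@dataclass
class DendrogramResult:
    """Class-mean Euclidean distances and their agglomerative tree."""

    labels: list[str]  # class labels in distance-matrix order
    distances: pd.DataFrame  # symmetric class-by-class Euclidean distances
    linkage: np.ndarray  # scipy linkage matrix

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_nested(self) -> dict:
        """Nested merge structure (labels at leaves, heights at merges)."""

        def node(i: int):
            n = len(self.labels)
            if i < n:
                return {"label": self.labels[i]}
            row = self.linkage[i - n]
            return {
                "height": float(row[2]),
                "children": [node(int(row[0])), node(int(row[1]))],
            }

        return node(len(self.labels) + len(self.linkage) - 1)


def class_distance_dendrogram(
    features: pd.DataFrame,
    zscore: bool = False,
    method: str = "average",
) -> DendrogramResult:
    """Cluster class-mean postures by Euclidean distance.

    Classes are object x modality pairs; classes without trials are dropped
    with a warning. Angles are used in degrees without standardization by
    default (``zscore=True`` standardizes each joint before distances).
    """
    cols = _angle_columns(features)
    if not cols:
        raise ValueError("no angle columns in the feature table")
    data = features.copy()
    if zscore:
        sd = data[cols].std(ddof=0).replace(0.0, 1.0)
        data[cols] = (data[cols] - data[cols].mean()) / sd
    grouped = data.groupby(["object", "modality"], sort=True)[cols].mean()
    n_expected = features["object"].nunique() * features["modality"].nunique()
    if len(grouped) < n_expected:
        warnings.warn("empty object x modality classes excluded from the dendrogram")
    if len(grouped) < 2:
        raise ValueError("need at least 2 classes for a dendrogram")
    labels = [f"{'V' if m == 'visual' else 'T'}-{o}" for o, m in grouped.index]
    means = grouped.to_numpy()
    diff = means[:, None, :] - means[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    z = linkage(squareform(dist, checks=False), method=method)
    return DendrogramResult(
        labels=labels,
        distances=pd.DataFrame(dist, index=labels, columns=labels),
        linkage=z,
    )


def kinematic_decoding(
    features: pd.DataFrame,
    scheme: str = "full",
    seed: int = 0,
    reg: float = 0.1,
) -> ConfusionMatrix:
    """Trial-balanced leave-one-out LDA on grasp postures.

    ``scheme`` selects the label set: ``"full"`` (object x modality, 12
    classes), ``"object"`` (6) or ``"modality"`` (2).
    """
    cols = _angle_columns(features)
    x = features[cols].to_numpy()
    objects = features["object"].to_numpy()
    modalities = features["modality"].to_numpy()
    labels, classes = labels_for_scheme(objects, modalities, scheme)
    conditions, _ = labels_for_scheme(objects, modalities, "full")
    return balanced_loo(
        x, labels, classes=classes, groups=conditions, seed=seed, reg=reg
    )
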
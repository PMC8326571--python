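"""Trial-balanced leave-one-out LDA decoding with confusion matrices.

The decoder is linear discriminant analysis with a shared (pooled
within-class) covariance, equal class priors and diagonal loading for
stability when the feature count approaches the per-class trial count
(e.g. ~60 motor-cortex units vs ~13 balanced training trials per class).
Evaluation is leave-one-out: for every held-out trial the remaining trials
of every class are subsampled to the global minimum class count before
fitting, so no condition is over-represented in training. Results are
row-normalized confusion matrices (rows: instructed class, columns:
decoded class, in percent) whose diagonal mean is the reported accuracy;
uniform guessing over K classes yields the chance level 100/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MODALITIES, OBJECTS
from .types import SpikeData


@dataclass(frozen=True)
class EpochSpec:
    """A fixed-length decoding window anchored to a trial event."""

    name: str
    align_event: str
    window_ms: tuple[float, float]

    @property
    def length_ms(self) -> float:
        return self.window_ms[1] - self.window_ms[0]


#: The three standard 500 ms decoding epochs: first and last 500 ms of the
#: memory period, and the 500 ms from movement onset (grasp).
EPOCH_SPECS: dict[str, EpochSpec] = {
    "early_memory": EpochSpec("early_memory", "memory_start", (0.0, 500.0)),
    "late_memory": EpochSpec("late_memory", "go", (-500.0, 0.0)),
    "grasp": EpochSpec("grasp", "movement_onset", (0.0, 500.0)),
}


@dataclass
class FeatureMatrix:
    """Trials-by-features matrix with per-trial condition labels."""

    x: np.ndarray  # (n_trials, n_features)
    objects: np.ndarray  # (n_trials,)
    modalities: np.ndarray  # (n_trials,)
    trial_ids: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.isnan(self.x).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class ConfusionMatrix:
    """Row-normalized classification outcome.

    ``matrix`` rows are instructed classes, columns decoded classes, in
    percent; every row sums to 100. ``accuracy`` is the mean of the
    diagonal, i.e. balanced accuracy over classes.
    """

    classes: list[str]
    matrix: pd.DataFrame  # percent
    n_per_class: pd.Series
    accuracy: float
    seed: int | None = None
    fold_log: list[dict] | None = None  # per-fold training composition

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def chance(self) -> float:
        return chance_level(self.k)


def chance_level(k: int) -> float:
    """Accuracy (%) of uniform random guessing over k classes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 100.0 / k


def labels_for_scheme(
    objects: np.ndarray, modalities: np.ndarray, scheme: str
) -> tuple[np.ndarray, list[str]]:
    """Map per-trial (object, modality) to class labels for a scheme.

    ``"full"`` gives the 12 object-x-modality classes ordered all-visual
    then all-tactile (V-sphere ... T-box, the standard axis convention);
    ``"object"`` collapses modalities; ``"modality"`` collapses objects.
    """
    objects = np.asarray(objects)
    modalities = np.asarray(modalities)
    present = [o for o in OBJECTS if o in set(objects)] or sorted(set(objects))
    if scheme == "full":
        classes = [
            f"{'V' if m == 'visual' else 'T'}-{o}" for m in MODALITIES for o in present
        ]
        labels = np.array(
            [
                f"{'V' if m == 'visual' else 'T'}-{o}"
                for o, m in zip(objects, modalities)
            ]
        )
    elif scheme == "object":
        classes = list(present)
        labels = objects.astype(str)
    elif scheme == "modality":
        classes = [m for m in MODALITIES if m in set(modalities)]
        labels = modalities.astype(str)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return labels, classes


def epoch_rates(
    spikes: SpikeData, trials: pd.DataFrame, epoch: EpochSpec
) -> FeatureMatrix:
    """Mean firing rate (Hz) of every QC-passing unit in the epoch window."""
    passing = spikes.passing()
    unit_ids = passing.unit_ids
    correct = trials[trials["outcome"] == "correct"]
    anchors = correct[epoch.align_event].to_numpy(dtype=float)
    lo, hi = epoch.window_ms
    x = np.empty((len(correct), len(unit_ids)))
    for j, uid in enumerate(unit_ids):
        t = passing.trains[uid]
        counts = np.searchsorted(t, anchors + hi) - np.searchsorted(t, anchors + lo)
        x[:, j] = counts / (epoch.length_ms / 1000.0)
    return FeatureMatrix(
        x=x,
        objects=correct["object"].to_numpy(),
        modalities=correct["modality"].to_numpy(),
        trial_ids=correct["trial_id"].to_numpy(),
        feature_names=list(unit_ids),
    )


@dataclass
class LDAModel:
    """LDA with pooled covariance, diagonal loading and equal priors."""

    classes: list[str]
    means: np.ndarray  # (K, p)
    cov: np.ndarray  # (p, p), regularized pooled within-class covariance
    reg: float

    def discriminant_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        w = np.linalg.solve(self.cov, self.means.T)  # (p, K)
        return x @ w - 0.5 * np.einsum("kp,pk->k", self.means, w)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax of the linear discriminant score; ties resolve to the
        lowest class index."""
        scores = self.discriminant_scores(x)
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]


def lda_fit(
    x: np.ndarray,
    labels: np.ndarray,
    classes: list[str] | None = None,
    reg: float = 0.1,
) -> LDAModel:
    """Fit LDA: class means plus pooled within-class covariance.

    ``reg`` scales the diagonal loading: ``lambda = reg * mean(diag(S))``
    is added to the pooled covariance S, which keeps the fit well-posed
    when features outnumber balanced training trials or columns are
    collinear.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    n, p = x.shape
    means = np.empty((len(classes), p))
    scatter = np.zeros((p, p))
    for k, c in enumerate(classes):
        xc = x[labels == c]
        if len(xc) < 1:
            raise ValueError(f"class {c!r} has no training trials")
        means[k] = xc.mean(axis=0)
        d = xc - means[k]
        scatter += d.T @ d
    dof = max(n - len(classes), 1)
    cov = scatter / dof
    lam = reg * np.trace(cov) / p
    if lam <= 0:
        lam = 1e-9
    return LDAModel(classes=list(classes), means=means, cov=cov + lam * np.eye(p), reg=reg)


def balanced_loo(
    x: np.ndarray,
    labels: np.ndarray,
    classes: list[str] | None = None,
    groups: np.ndarray | None = None,
    seed: int = 0,
    reg: float = 0.1,
    n_balance_draws: int = 1,
    collect_fold_log: bool = False,
) -> ConfusionMatrix:
    """Leave-one-out LDA with per-fold trial balancing.

    For every held-out trial, the remaining trials of each balancing group
    are subsampled (seeded) to the global minimum remaining group count
    before fitting. ``groups`` defaults to the class labels; when decoding
    collapsed labels (e.g. modality only) pass the full condition labels
    (object x modality) instead, so every condition — not just every
    decoded class — contributes equally to training. That keeps, say, the
    object composition of the two modality classes identical, which is
    exactly the over-representation the balancing step exists to prevent.

    With ``n_balance_draws > 1`` the prediction per fold is a majority vote
    over independent balancing draws. The result is deterministic for a
    fixed seed.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(set(labels.tolist()))
    class_index = {c: k for k, c in enumerate(classes)}
    counts = np.array([np.sum(labels == c) for c in classes])
    if (counts < 2).any():
        bad = [c for c, n in zip(classes, counts) if n < 2]
        raise ValueError(f"every class needs >= 2 trials; too few in {bad}")
    if groups is None:
        groups = labels
    groups = np.asarray(groups)
    group_levels = sorted(set(groups.tolist()))
    rng = np.random.default_rng(seed)
    k = len(classes)
    confusion = np.zeros((k, k))
    n_skipped = 0
    fold_log: list[dict] | None = [] if collect_fold_log else None
    for t in range(len(labels)):
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[t] = False
        idx_by_group = [
            np.flatnonzero(train_mask & (groups == g)) for g in group_levels
        ]
        m = min(len(idx) for idx in idx_by_group)
        if m < 1:
            n_skipped += 1
            continue
        votes = np.zeros(k)
        for _ in range(n_balance_draws):
            chosen = np.concatenate(
                [rng.choice(idx, size=m, replace=False) for idx in idx_by_group]
            )
            model = lda_fit(x[chosen], labels[chosen], classes=classes, reg=reg)
            pred = model.predict(x[t : t + 1])[0]
            votes[class_index[pred]] += 1
            if fold_log is not None:
                train_labels = labels[chosen]
                fold_log.append(
                    {
                        "held_out": t,
                        "per_group": m,
                        "class_counts": {
                            c: int(np.sum(train_labels == c)) for c in classes
                        },
                    }
                )
        confusion[class_index[labels[t]], np.argmax(votes)] += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} folds skipped (class collapsed after removal)")
    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(row_sums > 0, 100.0 * confusion / row_sums, 0.0)
    evaluated = row_sums[:, 0] > 0
    accuracy = float(np.diag(percent)[evaluated].mean()) if evaluated.any() else float("nan")
    return ConfusionMatrix(
        classes=list(classes),
        matrix=pd.DataFrame(percent, index=classes, columns=classes),
        n_per_class=pd.Series(confusion.sum(axis=1), index=classes, dtype=int),
        accuracy=accuracy,
        seed=seed,
        fold_log=fold_log,
    )


def marginal_decode(
    features: FeatureMatrix,
    scheme: str,
    seed: int = 0,
    reg: float = 0.1,
    n_balance_draws: int = 1,
) -> ConfusionMatrix:
    """Balanced LOO decoding after collapsing labels to one scheme.

    ``scheme="object"`` decodes the six objects ignoring modality;
    ``scheme="modality"`` decodes visual vs tactile ignoring objects;
    ``scheme="full"`` keeps all 12 conditions.
    """
    labels, classes = labels_for_scheme(features.objects, features.modalities, scheme)
    conditions, _ = labels_for_scheme(features.objects, features.modalities, "full")
    return balanced_loo(
        features.x,
        labels,
        classes=classes,
        groups=conditions,
        seed=seed,
        reg=reg,
        n_balance_draws=n_balance_draws,
    )


def decode_epochs(
    spikes: SpikeData,
    trials: pd.DataFrame,
    schemes: tuple[str, ...] = ("full", "object", "modality"),
    epochs: tuple[str, ...] = ("early_memory", "late_memory", "grasp"),
    areas: tuple[str, ...] | None = None,
    seed: int = 0,
    reg: float = 0.1,
) -> pd.DataFrame:
    """Accuracy table over epochs, schemes and (optionally) areas.

    Returns one row per (area, epoch, scheme) with the balanced-LOO
    accuracy and the matching chance level.
    """
    rows = []
    area_list = list(areas) if areas else [None]
    for area in area_list:
        sub = spikes
        if area is not None:
            units = spikes.units[spikes.units["area"] == area]
            sub = SpikeData(
                units=units.reset_index(drop=True),
                trains={u: spikes.trains[u] for u in units["unit_id"]},
                duration_ms=spikes.duration_ms,
            )
        for epoch_name in epochs:
            fm = epoch_rates(sub, trials, EPOCH_SPECS[epoch_name])
            for scheme in schemes:
                cm = marginal_decode(fm, scheme, seed=seed, reg=reg)
                rows.append(
                    dict(
                        area=area or "all",
                        epoch=epoch_name,
                        scheme=scheme,
                        accuracy_pct=cm.accuracy,
                        chance_pct=cm.chance,
                        n_classes=cm.k,
                        n_trials=int(cm.n_per_class.sum()),
                    )
                )
    return pd.DataFrame(rows)
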
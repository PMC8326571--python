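"""LDA decoding: epoch features, classifier correctness against oracles,
balanced leave-one-out behavior and chance levels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import graspflow as gf
from graspflow.decode import (
    EPOCH_SPECS,
    balanced_loo,
    chance_level,
    epoch_rates,
    labels_for_scheme,
    lda_fit,
    marginal_decode,
)
from graspflow.types import SpikeData

from conftest import make_trial, trials_frame


def spike_data(trains, duration_ms):
    units = pd.DataFrame(
        {
            "unit_id": list(trains),
            "area": "M1",
            "n_spikes": [len(t) for t in trains.values()],
            "mean_rate_hz": [len(t) / (duration_ms / 1e3) for t in trains.values()],
            "qc_pass": True,
        }
    )
    return SpikeData(
        units=units,
        trains={k: np.sort(np.asarray(v, float)) for k, v in trains.items()},
        duration_ms=duration_ms,
    )


class TestEpochRates:
    def test_count_to_rate_conversion(self):
        trial = make_trial()
        t0 = trial["memory_start"]
        trains = {"u0": t0 + np.array([10.0, 50.0, 120.0, 300.0, 499.0])}
        spikes = spike_data(trains, trial["hold_end"] + 1000.0)
        fm = epoch_rates(spikes, trials_frame([trial]), EPOCH_SPECS["early_memory"])
        assert fm.x[0, 0] == pytest.approx(10.0)  # 5 spikes / 0.5 s

    def test_silent_unit_rate_zero(self):
        trial = make_trial()
        spikes = spike_data({"u0": []}, trial["hold_end"] + 1000.0)
        fm = epoch_rates(spikes, trials_frame([trial]), EPOCH_SPECS["grasp"])
        assert fm.x[0, 0] == 0.0

    def test_memory_epoch_windows(self):
        # early memory starts at memory onset; late memory ends at the go cue
        trial = make_trial(memory_ms=1400.0)
        just_inside_early = trial["memory_start"] + 499.0
        just_inside_late = trial["go"] - 1.0
        gap_spike = trial["memory_start"] + 700.0  # in neither 500 ms epoch
        spikes = spike_data(
            {"u0": [just_inside_early, just_inside_late, gap_spike]},
            trial["hold_end"] + 1000.0,
        )
        early = epoch_rates(spikes, trials_frame([trial]), EPOCH_SPECS["early_memory"])
        late = epoch_rates(spikes, trials_frame([trial]), EPOCH_SPECS["late_memory"])
        assert early.x[0, 0] == pytest.approx(2.0)  # one spike in 500 ms
        assert late.x[0, 0] == pytest.approx(2.0)

    def test_only_qc_passing_units_used(self):
        trial = make_trial()
        spikes = spike_data({"u0": [], "u1": []}, trial["hold_end"] + 1000.0)
        spikes.units.loc[0, "qc_pass"] = False
        fm = epoch_rates(spikes, trials_frame([trial]), EPOCH_SPECS["grasp"])
        assert fm.feature_names == ["u1"]


class TestLDA:
    def test_two_class_boundary_at_midpoint(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])[:, None]
        y = np.array(["a"] * 200 + ["b"] * 200)
        model = lda_fit(x, y, reg=1e-9)
        assert model.predict(np.array([[4.9]]))[0] == "a"
        assert model.predict(np.array([[5.1]]))[0] == "b"

    def test_tie_breaks_to_lowest_class_index(self):
        x = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array(["a", "a", "b", "b"])
        model = lda_fit(x, y, reg=1.0)
        # exactly between symmetric classes: scores tie, lowest index wins
        assert model.predict(np.array([[1.0]]))[0] == "a"

    def test_predictions_match_mahalanobis_nearest_mean(self):
        # oracle: explicit (x - mu)' S^-1 (x - mu) with the same regularized
        # pooled covariance, equal priors
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_class, p = rng.integers(8, 15), rng.integers(2, 6)
            k = int(rng.integers(2, 5))
            means = rng.normal(0, 3, (k, p))
            x = np.vstack(
                [means[i] + rng.normal(0, 1, (n_class, p)) for i in range(k)]
            )
            y = np.repeat([f"c{i}" for i in range(k)], n_class)
            model = lda_fit(x, y, reg=0.1)
            test = rng.normal(0, 3, (30, p))
            pred = model.predict(test)
            cov_inv = np.linalg.inv(model.cov)
            d2 = np.array(
                [
                    [(t - m) @ cov_inv @ (t - m) for m in model.means]
                    for t in test
                ]
            )
            oracle = np.asarray(model.classes, dtype=object)[np.argmin(d2, axis=1)]
            assert np.array_equal(pred, oracle)

    def test_agrees_with_sklearn_on_well_conditioned_data(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(5)
        means = rng.normal(0, 2, (3, 4))
        x = np.vstack([m + rng.normal(0, 1, (40, 4)) for m in means])
        y = np.repeat(["a", "b", "c"], 40)
        ours = lda_fit(x, y, reg=1e-12)
        ref = LinearDiscriminantAnalysis().fit(x, y)
        test = rng.normal(0, 2, (50, 4))
        assert np.array_equal(ours.predict(test), ref.predict(test))

    def test_duplicate_columns_fit_with_regularization(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(20, 3))
        x = np.hstack([base, base])  # rank-deficient
        y = np.repeat(["a", "b"], 10)
        model = lda_fit(x, y, reg=0.1)
        assert model.predict(x).shape == (20,)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.zeros((2, 1)), np.array(["a", "a"]), classes=["a", "b"])


class TestBalancedLOO:
    def test_perfect_separation_gives_identity(self):
        rng = np.random.default_rng(2)
        means = np.eye(4) * 50.0
        x = np.vstack([m + rng.normal(0, 0.1, (6, 4)) for m in means])
        y = np.repeat([f"c{i}" for i in range(4)], 6)
        cm = balanced_loo(x, y, seed=0)
        assert cm.accuracy == 100.0
        assert np.allclose(np.diag(cm.matrix.to_numpy()), 100.0)

    def test_rows_sum_to_hundred(self, fixed15_session):
        fm = epoch_rates(
            fixed15_session.spikes,
            fixed15_session.trials,
            EPOCH_SPECS["grasp"],
        )
        cm = marginal_decode(fm, "full", seed=4)
        assert np.allclose(cm.matrix.sum(axis=1), 100.0)

    def test_same_seed_reproduces_matrix(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(48, 5))
        y = np.repeat(["a", "b", "c", "d"], 12)
        cm1 = balanced_loo(x, y, seed=9)
        cm2 = balanced_loo(x, y, seed=9)
        assert cm1.matrix.equals(cm2.matrix)

    def test_every_fold_is_balanced(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 3))
        y = np.array(["a"] * 10 + ["b"] * 12 + ["c"] * 8)
        cm = balanced_loo(x, y, seed=0, collect_fold_log=True)
        assert len(cm.fold_log) == 30
        for fold in cm.fold_log:
            counts = set(fold["class_counts"].values())
            assert len(counts) == 1  # all classes contribute equally
            assert counts.pop() == fold["per_group"]

    def test_too_few_trials_rejected(self):
        x = np.zeros((3, 2))
        y = np.array(["a", "a", "b"])
        with pytest.raises(ValueError, match="needs >= 2"):
            balanced_loo(x, y)


class TestSchemes:
    def test_chance_levels(self):
        assert chance_level(12) == pytest.approx(8.3333, abs=1e-3)
        assert chance_level(6) == pytest.approx(16.6667, abs=1e-3)
        assert chance_level(1) == 100.0
        with pytest.raises(ValueError):
            chance_level(0)

    def test_modality_collapse_counts(self):
        objects = np.repeat(list(gf.OBJECTS), 30)
        modalities = np.tile(["visual", "tactile"], 90)
        labels, classes = labels_for_scheme(objects, modalities, "modality")
        assert classes == ["visual", "tactile"]
        assert (pd.Series(labels).value_counts() == 90).all()

    def test_full_scheme_orders_visual_before_tactile(self):
        objects = np.array(["sphere", "box"])
        modalities = np.array(["visual", "tactile"])
        _, classes = labels_for_scheme(objects, modalities, "full")
        assert classes[0].startswith("V-")
        assert classes[-1].startswith("T-")
        assert len(classes) == 4

    def test_object_collapse_of_separable_conditions_is_identity(self):
        # object-specific centers with a small modality shift: collapsing
        # the 12 conditions to objects decodes perfectly
        rng = np.random.default_rng(4)
        object_centers = rng.normal(0, 60, (6, 6))
        shift = rng.normal(0, 1.0, 6)
        centers = np.vstack([object_centers + s * shift for s in (+1, -1)])
        x = np.vstack([c + rng.normal(0, 0.1, (5, 6)) for c in centers])
        objects = np.repeat(np.tile(list(gf.OBJECTS), 2), 5)
        modalities = np.repeat(["visual"] * 6 + ["tactile"] * 6, 5)
        fm = gf.FeatureMatrix(
            x=x, objects=objects, modalities=modalities, trial_ids=np.arange(60)
        )
        cm = marginal_decode(fm, "object", seed=0)
        assert cm.accuracy == 100.0
        assert np.allclose(np.diag(cm.matrix.to_numpy()), 100.0)
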
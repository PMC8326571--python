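"""Generator contracts: determinism, schedule arithmetic, rate laws,
behavioral timing calibration and epoch structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import graspflow as gf
from graspflow.behavior import timing_table
from graspflow.synth import trial_epochs
from graspflow.synth.schedule import draw_condition_schedule
from graspflow.synth.spikes import _unit_segment_rates, build_rate_segments


class TestSchedule:
    def test_identical_inputs_reproduce_session(self, small_session):
        cfg = small_session.config
        gen = small_session.generator
        again = gf.generate_session(cfg=cfg, gen=gen, seed=5)
        assert again.trials.equals(small_session.trials)
        for uid in small_session.spikes.trains:
            assert np.array_equal(
                again.spikes.trains[uid], small_session.spikes.trains[uid]
            )
        for a, b in zip(again.kinematics, small_session.kinematics):
            assert np.array_equal(a.angles, b.angles)

    def test_fixed_count_gives_exact_trial_total(self):
        cfg = gf.TaskConfig(trials_per_condition_range=(15, 15))
        schedule, counts = draw_condition_schedule(cfg, seed=2)
        assert len(schedule) == 15 * 12
        assert all(c == 15 for c in counts.values())

    def test_condition_counts_in_configured_range(self, default_session):
        counts = default_session.trials.groupby(["object", "modality"]).size()
        assert len(counts) == 12
        assert counts.between(14, 18).all()

    def test_schedule_is_interleaved_not_blocked(self, default_session):
        # a random interleaving almost surely alternates modality early on
        first = default_session.trials["modality"].iloc[:40]
        assert first.nunique() == 2

    def test_invalid_unit_count_rejected(self):
        with pytest.raises(gf.ConfigError):
            gf.GeneratorSettings(unit_counts={"F5": 0})

    def test_invalid_trial_range_rejected(self):
        with pytest.raises(gf.ConfigError):
            gf.TaskConfig(trials_per_condition_range=(0, 5))


class TestEpochs:
    def test_epochs_tile_trial_without_gaps_or_overlap(self, default_session):
        for _, trial in default_session.trials.head(20).iterrows():
            epochs = trial_epochs(trial)
            assert epochs[0][1] == trial["trial_start"]
            assert epochs[-1][2] == trial["hold_end"]
            for (_, _, end), (_, start, _) in zip(epochs, epochs[1:]):
                assert end == start
            assert all(end >= start for _, start, end in epochs)

    def test_memory_duration_within_paradigm_bounds(self, default_session):
        memory = default_session.trials["go"] - default_session.trials["memory_start"]
        assert memory.between(1000, 1500).all()

    def test_grasp_reaction_within_go_window(self, default_session):
        rt = (
            default_session.trials["movement_onset"] - default_session.trials["go"]
        )
        assert (rt >= 0).all()
        assert (rt <= default_session.config.go_window_ms).all()


class TestSpikeSimulation:
    def _single_unit_setup(self, rate_hz, duration_s=1000.0):
        cfg = gf.TaskConfig()
        gen = gf.GeneratorSettings(
            unit_counts={"F5": 1},
            baseline_rate_range_hz=(rate_hz, rate_hz),
            object_tuned_fraction=0.0,
            modality_tuned_fraction=0.0,
        )
        gt = gf.make_ground_truth(cfg, gen, seed=7)
        trials = pd.DataFrame(columns=list(gf.types.TRIAL_COLUMNS))
        return gf.simulate_spike_trains(
            trials, gt, cfg, gen, seed=7, duration_ms=duration_s * 1000.0
        )

    def test_homogeneous_rate_matches_poisson_expectation(self):
        # 10 Hz for 1,000 s: count within 3 standard deviations of 10,000
        spikes = self._single_unit_setup(10.0)
        n = len(next(iter(spikes.trains.values())))
        assert abs(n - 10_000) <= 3 * np.sqrt(10_000)

    def test_zero_baseline_rate_gives_no_spikes(self):
        spikes = self._single_unit_setup(0.0)
        assert len(next(iter(spikes.trains.values()))) == 0

    def test_untuned_unit_rate_law_is_condition_independent(self, default_session):
        gt = default_session.ground_truth
        untuned = np.flatnonzero(
            ~gt.unit_table["object_tuned"] & ~gt.unit_table["modality_tuned"]
        )
        assert untuned.size > 0
        segments = build_rate_segments(
            default_session.trials,
            default_session.config,
            default_session.duration_ms,
        )
        for u in untuned[:5]:
            rates = _unit_segment_rates(gt, int(u), segments)
            for epoch in np.unique(segments["epoch"]):
                in_epoch = rates[segments["epoch"] == epoch]
                assert np.allclose(in_epoch, in_epoch[0])

    def test_untuned_gains_exactly_zero(self, default_session):
        gt = default_session.ground_truth
        untuned_obj = ~gt.unit_table["object_tuned"].to_numpy()
        assert np.all(gt.object_gain[untuned_obj] == 0.0)
        untuned_mod = ~gt.unit_table["modality_tuned"].to_numpy()
        assert np.all(gt.modality_gain[untuned_mod] == 0.0)

    def test_all_spikes_inside_recording(self, default_session):
        spikes = default_session.spikes
        for t in spikes.trains.values():
            if t.size:
                assert t[0] >= 0
                assert t[-1] <= spikes.duration_ms

    def test_adding_units_preserves_existing_trains(self, small_session):
        cfg = small_session.config
        bigger = gf.GeneratorSettings(unit_counts={"F5": 4, "AIP": 2, "M1": 3})
        grown = gf.generate_session(cfg=cfg, gen=bigger, seed=5)
        for uid in small_session.spikes.trains:
            assert np.array_equal(
                grown.spikes.trains[uid], small_session.spikes.trains[uid]
            )


class TestBehaviorTimes:
    def test_zero_dispersion_yields_exact_means(self):
        cfg = gf.TaskConfig(trials_per_condition_range=(2, 2))
        gen = gf.GeneratorSettings(
            grasp_rt_sigma=0.0,
            grasp_mt_sigma=0.0,
            exploration_rt_sigma=0.0,
            exploration_mt_sigma=0.0,
            unit_counts={"F5": 1},
        )
        s = gf.generate_session(cfg=cfg, gen=gen, seed=2, spikes=False, kinematics=False)
        rt = s.trials["movement_onset"] - s.trials["go"]
        assert np.allclose(rt, 259.0)
        visual = s.trials["modality"] == "visual"
        mt = s.trials["object_lifted"] - s.trials["movement_onset"]
        assert np.allclose(mt[visual], 308.0)
        assert np.allclose(mt[~visual], 310.0)

    def test_grasp_rt_mean_calibrated(self):
        # pooled sessions: empirical mean within 3 standard errors of 259 ms
        rts = []
        for seed in (21, 22, 23):
            s = gf.generate_session(seed=seed, spikes=False, kinematics=False)
            rts.append((s.trials["movement_onset"] - s.trials["go"]).to_numpy())
        rts = np.concatenate(rts)
        se = rts.std(ddof=1) / np.sqrt(len(rts))
        assert abs(rts.mean() - 259.0) <= 3 * se

    def test_exploration_slower_than_grasp(self, default_session):
        table = timing_table(default_session.trials).set_index(["phase", "metric"])
        expl_mt = table.loc[("exploration", "movement"), "mean_ms"]
        grasp_mt = table.loc[("grasp", "movement"), "mean_ms"]
        if isinstance(expl_mt, pd.Series):
            expl_mt, grasp_mt = expl_mt.mean(), grasp_mt.mean()
        assert expl_mt > grasp_mt

    def test_tactile_events_ordered(self, default_session):
        tactile = default_session.trials.query("modality == 'tactile'")
        assert (tactile["expl_movement_onset"] > tactile["cue_on"]).all()
        assert (tactile["exploration_lift"] > tactile["expl_movement_onset"]).all()
        assert (tactile["handrest_return"] <= tactile["cue_off"]).all()


class TestKinematicsSimulation:
    def test_zero_noise_recovers_canonical_posture(self):
        cfg = gf.TaskConfig(trials_per_condition_range=(1, 1), n_objects=2)
        gen = gf.GeneratorSettings(
            unit_counts={"F5": 1},
            posture_noise_deg=0.0,
            sensor_noise_deg=0.0,
            modality_offset_deg=0.0,
        )
        s = gf.generate_session(cfg=cfg, gen=gen, seed=9, spikes=False)
        objects = list(cfg.objects)
        for trace in s.kinematics:
            trial = s.trials.set_index("trial_id").loc[trace.trial_id]
            canonical = s.ground_truth.canonical_postures[
                objects.index(trial["object"])
            ]
            settled = trace.angles[trace.times > trial["object_lifted"] + 100]
            assert np.allclose(settled, canonical[None, :], atol=1e-9)

    def test_trace_starts_at_rest_posture(self, small_session):
        rest = small_session.ground_truth.rest_posture
        for trace in small_session.kinematics[:5]:
            # before movement onset the hand sits at rest (plus sensor noise)
            trial = small_session.trials.set_index("trial_id").loc[trace.trial_id]
            pre = trace.angles[trace.times < trial["movement_onset"]]
            assert np.abs(pre - rest[None, :]).mean() < 5 * small_session.generator.sensor_noise_deg

    def test_glove_rate_within_range(self, default_session):
        trace = default_session.kinematics[0]
        dt = np.diff(trace.times)
        rate = 1000.0 / dt.mean()
        lo, hi = default_session.config.glove_rate_hz_range
        assert lo - 1 <= rate <= hi + 1

    def test_modality_offset_moves_tactile_postures(self):
        cfg = gf.TaskConfig(trials_per_condition_range=(5, 5), n_objects=2)
        gen = gf.GeneratorSettings(
            unit_counts={"F5": 1},
            modality_offset_deg=30.0,
            posture_noise_deg=0.1,
            sensor_noise_deg=0.0,
        )
        s = gf.generate_session(cfg=cfg, gen=gen, seed=4, spikes=False)
        feats = gf.extract_grasp_features(s)
        cols = [c for c in feats.columns if c.startswith("angle_")]
        means = feats.groupby(["object", "modality"])[cols].mean()
        for obj in cfg.objects:
            gap = np.linalg.norm(
                means.loc[(obj, "visual")] - means.loc[(obj, "tactile")]
            )
            assert abs(gap - 30.0) < 3.0
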
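"""Reaction- and movement-time analysis of a synthetic session.

Reaction time (RT) runs from the go cue (or, in the tactile exploration
phase, the cue instruction) to handrest release; movement time (MT) from
release to the completed object lift. Exploration is slower than the
instructed grasp because the object is still unknown then — the grasp-phase
means are the signature that the animal already knows the object.
"""

import graspflow as gf
from graspflow.behavior import timing_summary, timing_table, validate_trials

session = gf.generate_session(seed=1, spikes=False, kinematics=False)
trials = validate_trials(session.trials.drop(columns="outcome"), session.config)
print(f"correct trials: {(trials['outcome'] == 'correct').sum()} / {len(trials)}")

print("\nRT/MT means (ms) per phase and modality:")
print(timing_table(trials).to_string(index=False))

summary = timing_summary(trials, "grasp", "reaction", bin_ms=5.0, cutoff_ms=550.0)
print(
    f"\ngrasp RT histogram: {summary.counts.sum()} trials in 5 ms bins up to "
    f"550 ms ({summary.n_beyond_cutoff} beyond cutoff), mean {summary.mean_ms:.0f} ms"
)
print("generator targets: exploration RT/MT 323/757 ms, grasp RT 259 ms")
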
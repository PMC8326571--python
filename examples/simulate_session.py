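"""Generate a synthetic delayed-grasping session and save it to disk.

A session bundles the trial/event table (6 objects x 2 sensory modalities,
14-18 trials per condition), spike trains from four cortical areas (F5,
AIP, M1, S1), joint-angle hand kinematics, and the generator's ground
truth. Everything is reproducible from the seed.
"""

import graspflow as gf

session = gf.generate_session(seed=1)

print(f"trials:            {session.n_trials}")
print(f"duration:          {session.duration_ms / 1000:.0f} s")
print(f"units:             {len(session.spikes.unit_ids)}")
print(session.spikes.units.groupby("area")["unit_id"].count().rename("units per area"))
counts = session.trials.groupby(["object", "modality"]).size()
print(f"trials/condition:  {counts.min()}-{counts.max()} (target 14-18)")

out = gf.save_session(session, "scratch/example_session")
print(f"session written to {out}/ (events.csv, spikes.csv, kinematics.csv, ...)")
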
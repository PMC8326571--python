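"""Epoch-wise population decoding of object and sensory modality.

Unit firing rates in three 500 ms epochs — early memory (first 500 ms of
the delay), late memory (last 500 ms before the go cue) and grasp (from
movement onset) — feed a trial-balanced leave-one-out LDA. The headline
dissociation: modality decoding falls toward its 50% chance by the grasp
epoch while object decoding rises far above its 16.7% chance.
"""

import graspflow as gf

session = gf.generate_session(seed=1, kinematics=False)
table = gf.decode_epochs(
    session.spikes,
    session.trials,
    schemes=("full", "object", "modality"),
    epochs=("early_memory", "late_memory", "grasp"),
    areas=("F5", "M1", "S1"),
    seed=1,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:6.1f}"))
print(
    "\naccuracy_pct is the mean confusion-matrix diagonal; chance_pct = 100/K."
    "\nNote modality accuracy dropping from early memory to grasp while"
    "\nobject accuracy rises - the sensory origin of the instruction fades"
    "\nas the movement itself takes over."
)
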
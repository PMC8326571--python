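"""Sliding-window ANOVA: fraction of tuned units over the trial.

Spike counts in 100 ms windows (stride 20 ms here) aligned to the go cue
are tested per unit with a two-way ANOVA (factors: object, sensory
modality) and Bonferroni-corrected over windows. The fraction of
significant units per area traces where each kind of information lives:
modality tuning peaks around cue/early memory and decays toward movement,
object tuning peaks during movement.
"""

import graspflow as gf

session = gf.generate_session(seed=1, kinematics=False)
binned = gf.bin_spikes(
    session.spikes,
    session.trials,
    align_event="go",
    span_ms=(-1500.0, 800.0),
    window_ms=100.0,
    stride_ms=20.0,
)
pvals = gf.sliding_anova(binned)
timecourses = gf.tuned_fraction(pvals, binned, alpha=0.05, correction="bonferroni")

print("peak tuned fraction per area and factor (time relative to go cue):")
for tc in sorted(timecourses, key=lambda t: (t.factor, t.area)):
    t_peak, frac = tc.peak()
    print(
        f"  {tc.area:>3s} {tc.factor:>8s}: {100 * frac:5.1f}% of {tc.n_units} units"
        f" at {t_peak:+6.0f} ms"
    )
print(
    "\nmodality peaks sit before the go cue (cue/early memory), object peaks"
    "\nafter it (movement) - the generator's injected structure, recovered."
)
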
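# Methods

This note documents the models, parameter choices and numerical decisions
behind `graspflow`, and what the synthetic validation does and does not
establish about real recordings.

## Task model

A session is a sequence of trials over 6 objects × 2 sensory modalities
(visual, tactile), scheduled as a random interleaving with per-condition
counts drawn uniformly from 14–18 (configurable, e.g. fixed at 15). Each
trial tiles into five epochs:

| epoch | duration | content |
|---|---|---|
| baseline | 500 ms | dark, hand at rest |
| cue | 700 ms (visual) / 2,000 ms (tactile, configurable ≤ 3,000 ms) | object illuminated, or reached, explored and briefly lifted in the dark |
| memory | uniform 1,000–1,500 ms | object held in memory, hand at rest |
| movement | go cue → object lift, response window 870 ms | instructed grasp |
| hold | 700 ms | object held lifted |

The paradigm only bounds tactile exploration at 3,000 ms; the generator
uses a fixed 2,000 ms exploration epoch so that exploration RT + MT plus a
200 ms return-to-handrest fit inside it. Tactile trials carry three extra
events (handrest release, exploration lift, handrest return) so that
exploration-phase RT/MT are defined analogously to the grasp phase, with
the cue instruction in place of the go cue.

Reaction and movement times are log-normal, parameterized by their
arithmetic mean and log-scale dispersion σ (σ = 0 degenerates to the exact
mean, which the tests exploit). Defaults: exploration RT 323 ms (σ 0.35),
exploration MT 757 ms (σ 0.35), grasp RT 259 ms (σ 0.25), grasp MT
308/310 ms visual/tactile (σ 0.2). The means are the empirical targets the
generator emulates; the dispersions are free parameters chosen to give
realistic right-skewed histograms, since only means are available to
calibrate against. Grasp RTs are resampled to respect the 870 ms response
window, so generated sessions contain only correct trials; the validator
(`behavior.validate_trials`) nevertheless checks epoch order, memory
bounds and response windows, because loaded real data will contain errors.

Histogram cutoffs (RT: 5 ms bins to 550 ms; MT: 10 ms bins to 1,000 ms)
are display conventions: values beyond the cutoff are dropped from the
histogram but kept in the mean.

## Spiking model

Each unit fires as an inhomogeneous Poisson process with piecewise-constant
rate

```
λ_u(t) = β_u · g_e · (1 + a_{u,e} · f_obj(o) + b_{u,e} · f_mod(m)),  clipped at 0
```

where `β_u ~ U(4, 20) Hz` is the unit's baseline rate, `g_e` a shared
per-epoch excitability gain (1.5 during movement, 1.2 during cue and hold,
1 elsewhere), `f_obj(o) ∈ [−1, 1]` the unit's random per-object tuning
score, and `f_mod(m) = ±1` for visual/tactile. Tuning gains `a`, `b` are
exactly zero for untuned units (40% of units are object-tuned and 40%
modality-tuned by independent Bernoulli draws, configurable). Epoch
profiles emulate the qualitative structure the analysis should recover:
object gain peaks in cue (0.8×) and movement (1.0×), modality gain peaks in
cue/early memory (1.0×) and decays to 0.05× by movement and hold. These
profiles are the generator's definition of the study's
modality-early/object-late dissociation; recovery tests check the analysis
finds them, not that nature looks this way.

Spikes are drawn by thinning a homogeneous process at the unit's maximum
rate, which is exact for piecewise-constant rates. Every unit owns an
independent counter-based random stream keyed by (master seed, unit
index) — for both its spikes and its latent traits — so enlarging the
population never perturbs existing units, and identical (config, seed)
reproduce sessions bit-for-bit.

## Kinematics model

Postures live in a D = 27 dimensional joint-angle space (a full hand model
with a seven-sensor glove heritage; the dimensionality is configurable and
nothing downstream depends on it). Each object has a canonical grasp
posture drawn uniformly per joint from 10–70°; in 27 dimensions such draws
are far apart, giving cleanly object-specific grips. A trial's settled
posture is canonical + modality offset (a fixed vector of configurable
magnitude along a random direction; **default 0**, because grips are
modality-independent in the modeled behavior) + N(0, 4²) posture noise.
The hand moves from rest to the settled posture along a minimum-jerk
profile (10τ³ − 15τ⁴ + 6τ⁵) spanning the movement epoch — only the settled
posture is analyzed, so the trajectory model is cosmetic — and samples at
a per-session glove rate drawn from 70–100 Hz, with 1° sensor noise.

The grasp feature is the arithmetic mean of all samples falling in
[lift + 450 ms, lift + 550 ms], without interpolation (irregular sampling
is handled by time-windowed averaging; at ≥ 70 Hz the window holds ≥ 7
samples). Class distances use degrees without per-joint standardization
(none is suggested by the modeled analysis); a `zscore` switch exists.
Dendrograms cluster class-mean postures (class = object × modality) with
average linkage — the linkage criterion is not dictated by the modeled
analysis and is configurable.

## Sliding ANOVA

Counts in 100 ms windows (stride 10 ms by default; figures in this
tradition look near-continuous, and the stride is configurable) are tested
per unit and window with a two-way fixed-effects ANOVA, main effects only:
with 14–18 trials per condition an interaction term is estimable and is
available behind a flag, but the modeled analysis names only the two
factors. Because the design is unbalanced, factors are tested by model
comparison (type-II sums of squares): F for factor A is the RSS drop from
adding A to the model already containing B, over the full additive model's
residual mean square. The implementation shares one QR decomposition per
design matrix across all units × windows, and its F values agree with
statsmodels' `anova_lm(typ=2)` to 1e-10. Columns with zero residual
variance yield p = 1 when the factor explains nothing and p = 0 otherwise.

Counts enter untransformed (a square-root variance-stabilizing option
exists). Significance uses α = 0.05 with Bonferroni correction whose
family is the number of windows per unit and factor — the family size is
genuinely ambiguous in this tradition, so it is documented and
configurable. A per-modality one-way object ANOVA (`per_modality_object`)
reproduces displays that separate visual and tactile trials. Type-I
control is verified empirically: on fully null 200-unit sessions the
per-unit family-wise error stays below 0.05 (Bonferroni over overlapping,
hence positively correlated, windows is conservative — measured ≈ 0.03).

## Decoding

Epoch features are mean firing rates (Hz) in three 500 ms windows: early
memory `[memory_start, +500)`, late memory `[go − 500, go)`, and grasp
`[movement_onset, +500)` — the grasp epoch is anchored at movement onset
because that is when the grip unfolds.

The classifier is LDA with pooled within-class covariance, equal priors
(balanced training makes empirical priors uniform anyway) and diagonal
loading `λ = 0.1 · mean(diag S)`, needed because unit counts can exceed
balanced per-class training counts (e.g. ~65 M1 units vs ~13 trials per
class). Ties in the score argmax resolve to the lowest class index.

Evaluation is leave-one-out with per-fold balancing at the **condition**
level: after removing the held-out trial, every object × modality cell is
subsampled to the global minimum remaining cell count. Balancing at the
condition level (rather than at the level of the decoded classes) matters
for collapsed schemes: when decoding modality alone, it keeps the object
composition of the two modality classes identical, removing an
object-composition artifact that otherwise biases leave-one-out accuracy
visibly below chance in the presence of strong object clustering. One
balancing draw per fold is the default; `n_balance_draws` averages over
repeated draws by majority vote.

Confusion matrices are row-normalized (instructed × decoded, percent);
accuracy is the mean diagonal, and chance for K classes is 100/K (8.33%
for 12, 16.67% for 6, 50% for 2). A small leave-one-out pessimism remains
even after balancing (the held-out trial is missing from its own class
mean); on label-independent features it is within the 3-standard-error
bands the calibration tests use.

## Broadband simulation and preprocessing

Channels map 1:1 to units (waveform sorting is out of scope; in
simulation the mapping is exact, and detection quality is scored against
ground-truth spike times). A channel is spike templates (biphasic,
negative-leading, ~1.6 ms, 80 µV trough placed at each spike time) + an
equal white/1-f noise mix (σ = 10 µV) + a common-mode artifact: slow
sinusoidal drift (40 µV), sparse broadband bursts (60 µV, 0.5 Hz), and a
continuous shared broadband component (8 µV), all along one per-channel
gain vector (gains U(0.7, 1.3)), so the artifact is genuinely rank-1. The
default template-to-noise ratio (8 σ troughs) defines the "default SNR"
detection fixture.

Preprocessing decisions:

* **Median high-pass**: 3.33 ms at 30 kS/s is 100 samples; a running
  median needs an odd window, so 101 is used.
* **"Non-causal" low-pass**: read as forward–backward filtering of the
  4th-order 5 kHz Butterworth design (zero phase, effective 8th-order
  magnitude), so spike trough times are not displaced.
* **PCA cancellation**: channels are unit-variance normalized; a component
  is common-mode artifact when ≥ 50% of channels have |loading| > 0.36,
  and flagged components are projected out (the flagged-components-are-kept
  reading is available behind a switch). The loading tested is the
  component–channel **correlation** (eigenvector entry × √eigenvalue):
  with raw unit-norm eigenvectors a fixed 0.36 threshold cannot work
  across array sizes (a uniformly-loaded component has entries 1/√C —
  0.41 at 6 channels but 0.18 at 32), whereas the correlation scale makes
  the same threshold meaningful at any channel count. Projecting one
  component out of C channels induces ≈ −1/(C−1) residual correlation
  among the rest; the residual-correlation acceptance check therefore uses
  a 32-channel fixture.
* **Detection**: negative crossings at 4.5 × median(|x|)/0.6745 (a robust
  noise estimate insensitive to the spikes themselves), 1 ms lockout,
  event time at the trough.
* **Unit QC**: mean rate over the full recording ≥ 1 Hz passes (boundary
  inclusive); idempotent.

## What the synthetic validation shows — and does not

Passing tests establish that every stage recovers what the generator
injected under its assumptions: Poisson spiking with epoch-constant rates,
Gaussian posture noise, rank-1 common-mode artifacts, stationary noise.
Real recordings violate all of these (bursting and refractory structure,
electrode drift, non-stationary artifacts, correlated noise across nearby
electrodes, sorting errors), so the suite validates the *analysis code*,
not the biological claims; the original recordings are not publicly
available, and reproducing their accuracies is explicitly out of scope.
Problem sizes in the test and acceptance runs (one session of ~190 trials
and 150–200 units; broadband fixtures of 16–32 channels × ~20 s) were
chosen as the smallest sizes at which the statistical checks have
meaningful power.

## Known limitations

* No spike sorting: detection-to-unit mapping is 1:1 per channel, valid
  only in simulation or for well-isolated single-unit channels.
* The tactile exploration epoch is a fixed duration with rest-posture
  kinematics; exploratory hand movement is not modeled (only settled
  grasps are analyzed).
* No inter-trial rate drift, adaptation or history dependence in the
  Poisson model; the type-I calibration inherits ANOVA's robustness to the
  count distribution at these trial counts rather than exact F-test
  assumptions.
* The leave-one-out chance bias, while controlled by condition-level
  balancing, is not exactly zero; chance calibration is asserted within
  3 binomial standard errors, not as equality.
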
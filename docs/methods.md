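# Methods

`kinelrp` implements an explainable-classification pipeline for wearable-
sensor kinematics: given per-trial 3D joint-angle time series recorded at
60 Hz during on-ice drills under two conditions (wearing protective
Equipment vs. NoEquipment), it extracts individual movements, builds
normalized fixed-length feature vectors, trains a shallow network to
classify the condition, and decomposes the network's decisions into
per-joint, per-cycle-percent relevance heatmaps via layer-wise relevance
propagation (LRP). Because raw recordings of this kind cannot ship with a
software package, a synthetic-kinematics generator with injectable, known
condition effects provides the test bed for every stage.

## Movement extraction

All rules operate on low-pass-filtered auxiliary signals. "Zero-lag
fourth-order Butterworth" is interpreted as a 4th-order design applied
forward then backward (`scipy.signal.filtfilt`): the phase response cancels
and the magnitude response is squared. The forward-only variant is available
via `FilterSpec(zero_lag=False)`.

* **Sprint / linear crossover** (cutoff 5 Hz): ice contacts of each skate
  are local minima of the filtered vertical foot velocity that are negative,
  separated by at least 0.3 s, with prominence at least 20% of the filtered
  signal's peak-to-peak range. A stride (crossover) is the half-open sample
  interval between two consecutive contacts of the same foot; three strides
  per foot are taken for the sprint (six per trial), one per foot for the
  crossover (two per trial). The minimum-separation and prominence values
  are package defaults — the extraction rule names the signal, not numeric
  thresholds — and are exposed as function arguments.
* **Slap shot** (cutoff 4 Hz): the shot side is the shoulder with the larger
  peak absolute filtered vertical angular velocity (a warning is raised when
  the peaks differ by less than 5%). The shot starts at the last sample, searching
  backward from the hand-velocity peak, at which the deflection is below 5%
  of the peak, and ends at the first post-peak sign reversal of the hand
  velocity (the puck strike stops the hand). The 5% start threshold is a
  package default, exposed as an argument.
* **Power turn** (cutoff 0.5 Hz): the circuit is split at every sign change
  of the filtered pelvis vertical angular velocity; the first and last
  (partial) segments are discarded, each remaining segment is one turn
  labelled clockwise (negative lobe) or counterclockwise (positive lobe).

Failure to extract the required number of movements raises
`TrialExclusionError`, a per-trial exclusion signal the caller may treat as
fatal or as a participant exclusion.

## Feature construction

Twelve degrees of freedom per side are retained (hip flexion/extension,
abduction/adduction, internal/external rotation; knee flexion/extension and
internal/external rotation; ankle flexion/extension and internal/external
rotation; shoulder flexion/extension, abduction/adduction, internal/external
rotation; elbow flexion/extension and pronation/supination). The wrist,
ankle abduction/adduction and knee abduction/adduction are excluded as
falling below the ~1° accuracy of the measurement system; an additional
reporting check (`flag_unreliable_dofs`) flags any retained DOF whose maximal
between-condition mean difference is below 1° pre-normalization, without
dropping it.

Each extracted movement is time-normalized to 100 cycle points by a cubic
spline through all samples evaluated at equally spaced cycle fractions
(resampling a 100-point trajectory is the identity; spline degree is a
package choice). Angles are then normalized participant-wise:

    x_norm(d) = ratio(d) * x / max_abs(d)

where `max_abs(d)` is the participant's maximum absolute angle for DOF `d`
pooled over **all** segments of **both** conditions (pooling prevents the
classifier from exploiting per-condition scaling artifacts), and `ratio(d)`
is a pre-set range-of-motion ratio relative to the largest-ROM joint
(shoulder abduction/adduction, ratio 1). The shipped ratio table is derived
from standard goniometry references and is fully overridable; its exact
values are deliberately generic defaults, not cohort measurements. All
features therefore lie in [-ratio(d), ratio(d)] ⊆ [-1, 1] and relative
magnitudes between joints are preserved.

The per-DOF 100-point trajectories are concatenated in catalog order into
one vector: 12 × 100 = 1200 values for the sprint (only the ipsilateral side
is used, the movement being symmetric) and 24 × 100 = 2400 values for the
bilateral drills (ipsilateral block first, then contralateral; for shots the
ipsilateral side is the shooting side, for turns the inside-facing side).
`ChannelMap` records the position ↔ (channel, time-point) bijection used by
every downstream map.

## Classifier and evaluation

`ShallowTanhClassifier` is a three-layer network — input, one hidden layer
with twice as many nodes as inputs and tanh activation, and a 2-node output
— trained with mini-batch SGD (batch 16, learning rate 0.01, at most 100
epochs; 50 are used for small shot datasets) on softmax cross-entropy.
The output nonlinearity/loss are a package choice (the standard pairing for
a 2-node classification output, and compatible with propagating relevance
from pre-softmax scores); the optimizer is plain SGD with optional momentum;
weights are Glorot-uniform initialized; a 10% random validation split with
patience-based early stopping is available but off by default (training runs
to the epoch budget). Fits are bit-reproducible under a fixed seed.

Evaluation is leave-one-subject-out (LOSO): one fold per participant,
trained on all other participants, tested on the held-out participant's
complete set of movements. Per-participant accuracy is `n_p / N_p * 100`;
the cohort figure is the arithmetic mean over participants. Per-fold seeds
are derived from the global seed and the participant id (CRC32, < 2^31), so
folds are independent but reproducible. All fold models are retained for the
relevance stage.

## Relevance propagation

Relevance is computed for correctly classified held-out movements only,
starting from the pre-softmax score of the true class, with the
epsilon-stabilized z-rule (ε = 1e-9 by default):

    R_j = Σ_k (a_j w_jk) / (z_k + ε·sign(z_k)) · R_k,   z_k = Σ_j a_j w_jk + b_k.

Bias relevance is absorbed rather than redistributed (standard toolbox
behaviour); with zero biases the rule conserves relevance exactly, which the
tests assert at 1e-6 relative. Relevances may be negative pre-rescale;
non-negativity is not asserted.

Each relevance pattern is smoothed within every DOF's 100-point block
independently — kernel (0.25, 0.5, 0.25), i.e. the current point keeps 50%
and each neighbour receives 25%, applied twice with edge-value replication;
the kernel sums to 1 so mass is preserved and repetition mimics a Gaussian.
Blocks never mix, so relevance cannot leak between joints. Per participant,
the smoothed patterns are averaged and L1-normalized (the normalization
choice that makes participants contribute equally regardless of their raw
relevance scale); the cohort map is the participant average min-max rescaled
to [0, 1] globally (per-map, not per-DOF). Marginal profiles are computed
from the rescaled map: the time profile sums over DOFs per cycle point, the
DOF profile sums over time, and the two share the same total by construction.

## Performance statistics

Performance variables (sprint time, crossover time, puck velocity in km/h)
are averaged per participant and condition, then compared with a two-sided
paired Student's t-test preceded by a Shapiro–Wilk check on the paired
differences; when normality is rejected the test still runs and the report
carries a flag. Identical paired vectors are reported as t = 0, p = 1 by
contract rather than the indeterminate 0/0. Percent change uses the
Equipment condition as baseline: `100·(a_i − b_i)/a_i`, averaged, with
counts of participants who improved/worsened/stayed equal.

## Synthetic data generator

Baseline per-DOF trajectories are sums of 1–3 harmonics of the movement
cycle with DOF-specific amplitudes (first harmonic 8–20°, fixed per DOF
across seeds so the catalog has a stable "shape"), not motion-capture
templates — sufficient for validating segmentation, classification and
attribution, and dependency-free. Participant random effects act
multiplicatively on harmonic amplitudes (relative sd ≈ participant_sd/20°)
and additively on baseline offsets (sd = participant_sd, default 2°);
within-trial white noise has sd `noise_sd` (default 1°). Per-participant
random streams are derived from the global seed by fixed offsets, so
extending a cohort never changes existing participants' data.

Condition effects are injected only into Equipment trials:
`x → scale·x + offset` inside a phase window [a, b]% of the cycle, blended
with cosine tapers over 5% of the cycle on each flank *outside* the window,
so the full effect holds on the window itself (making the injected magnitude
exactly recoverable from ensemble means) while avoiding hard edges that
would make attribution artificially easy.

Raw segmentation signals are constructed so a perfect detector recovers the
recorded truth events on noiseless data: foot vertical velocity has a sharp
symmetric negative dip centred on each truth contact sample plus a mid-swing
bump, alternating between feet by half a cycle; the power-turn pelvis signal
is a slow sinusoid (well inside the 0.5 Hz passband, so filtering preserves
its zero crossings) with half-lobes at the boundaries; the shot's hand and
shoulder signals are smooth half-sine deflections, with the truth start/end
computed from the noiseless signal by the detector's own 5%-threshold and
sign-reversal definitions. Trial layouts: sprint/crossover cover n_cycles+1
cycles (0.8 s and 1.0 s cycles respectively, 6 cycles default, contacts away
from the filter's edge transients), power turns cover 6 turns of 4 s plus
boundary half-turns, and the shot is a single 1.5 s movement with 2 s quiet
lead-in and tail.

What the generator does **not** emulate: realistic inter-joint coordination,
soft-tissue artifact, drift or magnetometer disturbance, asymmetric or
skill-dependent technique, and distributional properties of real cohorts
(no public description of those exists for this task). Passing tests
therefore demonstrate the pipeline's correctness and its ability to recover
known injected effects — not field performance on real recordings.

## Problem sizes of the packaged studies

The structural checks (feature dimensions, architecture, sample accounting
with the reference exclusion lists: 408 sprint strides from 17 participants,
136 crossovers from 17, 72 shots from 18, 384 turns from 16) run at full
catalog size. The stochastic studies in `kinelrp.studies` use scaled-down
designs chosen to keep a full validation run in minutes on one CPU while
preserving the properties under test:

* **Localization / separable-accuracy study**: sprint cohorts of 10
  participants, 2 trials per condition, a 6-DOF catalog subset, 50 cycle
  points (input 300, hidden 600), 40 epochs, 10° shoulder-flexion offset at
  40–60% of the cycle, 2° noise; 10 seeded replicates.
* **Label-shuffle study**: 6 participants, 3-DOF subset, 25 cycle points,
  20 epochs, 20 shuffled replicates.
* **t-test calibration**: 1000 null replicates at n = 17.

## Known limitations

* The exact numeric thresholds of the original extraction rules (contact
  prominence, shot-start fraction) are not recoverable from their
  description; the defaults here are reasonable package choices and every
  one is overridable.
* The ROM ratio table ships generic goniometry-based defaults.
* LRP is implemented for this architecture only (dense 3-layer tanh);
  convolutional/recurrent variants and other attribution methods are out of
  scope.
* Real-data accuracies and p-values are not reproducible without the
  original recordings; the package validates structure and recoverability of
  known injected effects instead.
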
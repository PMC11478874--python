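# kinelrp

Explainable classification of equipment-induced movement restrictions from
wearable-sensor (IMU) joint-angle kinematics.

Protective sports equipment restricts natural movement, but *where* in the
body and *when* in the movement cycle it does so is hard to quantify. This
package implements a pipeline that answers that question for on-ice hockey
drills (sprint, linear crossover, slap shot, power turn) recorded with a
full-body IMU suit at 60 Hz under two conditions (Equipment / NoEquipment):

1. **Movement extraction** — drill-specific rules on zero-lag 4th-order
   Butterworth-filtered auxiliary signals: ice contacts from vertical foot
   velocity (5 Hz cutoff) bound strides and crossovers; shoulder angular
   velocity and hand vertical velocity (4 Hz) bound the slap shot; sign
   changes of pelvis vertical angular velocity (0.5 Hz) split power turns.
2. **Feature construction** — each movement's 12 (unilateral) or 24
   (bilateral) retained joint-angle DOFs are time-normalized to 100 cycle
   points by cubic splines, scaled participant-wise to
   `x_norm = ratio(d) · x / max_abs(d)` (ratio-preserving normalization into
   [-1, 1]) and concatenated into a 1200- or 2400-length vector.
3. **Classification** — a shallow network (input *n*, hidden *2n* with tanh,
   2 outputs; mini-batch SGD, batch 16, learning rate 0.01, ≤ 100 epochs)
   classifies the condition, evaluated leave-one-subject-out: per-participant
   accuracy `n_p/N_p·100`, averaged across participants.
4. **Relevance propagation** — epsilon-rule LRP
   (`R_j = Σ_k a_j w_jk / (z_k + ε·sign z_k) · R_k`) on correctly classified
   held-out movements, smoothed per DOF block with the (0.25, 0.5, 0.25)
   kernel applied twice, participant-averaged and L1-normalized, cohort-
   averaged and min-max rescaled to [0, 1] — yielding a DOF × cycle-percent
   relevance heatmap whose marginal profiles show *which joints* and *which
   movement phases* drive the classification.
5. **Performance statistics** — Shapiro–Wilk-checked paired t-tests and
   percent-change summaries for drill times / puck velocity.

A synthetic-kinematics generator (`kinelrp.synthetic`) produces cohorts with
participant random effects, sensor noise, ground-truth event indices and
*known injected condition effects* (e.g. "+10° on shoulder flexion at 40–60%
of the stride"), so every stage — including whether the relevance maps
recover the true location of an effect — is testable end to end.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Run a scaled-down sprint study with a known restriction and ask the
relevance maps where it is:

```python
import numpy as np
from kinelrp.studies import separable_sprint_run

dataset, summary, extras = separable_sprint_run(seed=1)
print("X shape:", dataset.X.shape)
print("mean LOSO accuracy: %.2f%%" % summary.mean_accuracy)
prof = extras["profiles"]
blocks = dataset.channel_map.blocks
for i in np.argsort(prof.dof_profile)[::-1][:3]:
    print(f"{blocks[i]:20s} dof_profile={prof.dof_profile[i]:.2f}")
peak = 100 * np.argmax(prof.time_profile) / dataset.channel_map.n_points
print("time-profile peak at %.0f%% of cycle" % peak)
```

Output:

```
X shape: (240, 300)
mean LOSO accuracy: 98.33%
shoulder_flexext     dof_profile=15.52
shoulder_abdadd      dof_profile=5.71
ankle_flexext        dof_profile=5.13
time-profile peak at 50% of cycle
```

The cohort is 10 synthetic participants × 24 strides, each a 300-length
feature vector (6 DOFs × 50 cycle points). The classifier separates the
conditions almost perfectly (98.33% mean LOSO accuracy), and the cohort
relevance map ranks shoulder flexion/extension — the DOF carrying the
injected 10° restriction — far above every other joint, with the
time-profile peak at 50% of the cycle, inside the injected 40–60% window:
the attribution recovers both the *joint* and the *phase* of the restriction.

There is also a CLI covering each stage:

```sh
kinelrp synth --drill sprint --participants 10 --seed 1 --out trials/
kinelrp segment --drill sprint --in trials/ --out segments.json
kinelrp featurize --drill sprint --in trials/ --segments segments.json --out features.csv
kinelrp train --features features.csv --seed 1 --out models/
kinelrp explain --features features.csv --seed 1 --out relevance/
kinelrp run --config run.yaml --out results/   # everything from a YAML config
```

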
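"""Packaged simulation studies: the scaled-down synthetic experiments used to
validate the pipeline's core scientific properties.

Each study fixes its own problem size (participants, DOF subset, cycle
points, epochs) as a package design choice; docs/methods.md discusses the
sizes.  All randomness derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import DEFAULT_CATALOG
from .mlp import loso_evaluate
from .performance import paired_t
from .pipeline import DrillRunConfig, run_drill
from .relevance import cohort_relevance_from_loso
from .synthetic import EffectSpec

#: DOF subset for the scaled-down sprint studies (half the retained set).
REDUCED_DOFS = (
    "hip_flexext",
    "knee_flexext",
    "ankle_flexext",
    "shoulder_flexext",
    "shoulder_abdadd",
    "elbow_flexext",
)

#: The injected restriction the localization study must recover.
LOCALIZATION_EFFECT = EffectSpec(
    dof="shoulder_flexext", window=(40.0, 60.0), offset_deg=10.0
)


def _reduced_catalog():
    return DEFAULT_CATALOG.subset(list(REDUCED_DOFS))


def separable_sprint_run(
    seed: int,
    n_participants: int = 10,
    n_points: int = 50,
    max_epochs: int = 40,
    noise_sd: float = 2.0,
):
    """Generate/segment/featurize/LOSO-train a strongly separable sprint
    cohort (10-degree shoulder-flexion restriction, 2-degree noise)."""
    cfg = DrillRunConfig(
        drill="sprint",
        n_participants=n_participants,
        effects=(LOCALIZATION_EFFECT,),
        participant_sd=2.0,
        noise_sd=noise_sd,
        n_points=n_points,
        train=True,
        clf_params={"max_epochs": max_epochs},
    )
    return run_drill(cfg, seed=seed, catalog=_reduced_catalog())


@dataclass
class LocalizationOutcome:
    top_dof: str
    time_peak_pct: float
    dof_ranked_first: bool
    peak_in_window: bool
    mean_accuracy: float

    @property
    def success(self) -> bool:
        return self.dof_ranked_first and self.peak_in_window


def localization_study(seed: int) -> LocalizationOutcome:
    """One replicate of the effect-localization experiment: does the cohort
    relevance map rank the restricted DOF first and place the time-profile
    peak inside (a neighbourhood of) the injected 40-60% window?"""
    dataset, summary, extras = separable_sprint_run(seed)
    profiles = extras["profiles"]
    blocks = dataset.channel_map.blocks
    top_dof = blocks[int(np.argmax(profiles.dof_profile))]
    n_points = dataset.channel_map.n_points
    time_peak_pct = 100.0 * float(np.argmax(profiles.time_profile)) / n_points
    return LocalizationOutcome(
        top_dof=top_dof,
        time_peak_pct=time_peak_pct,
        dof_ranked_first=(top_dof == LOCALIZATION_EFFECT.dof),
        peak_in_window=(35.0 <= time_peak_pct <= 65.0),
        mean_accuracy=summary.mean_accuracy,
    )


def localization_success_rate(seed: int, n_replicates: int = 10) -> tuple[int, list]:
    outcomes = [localization_study(seed + 1000 * r) for r in range(n_replicates)]
    return sum(o.success for o in outcomes), outcomes


def shuffled_label_study(
    seed: int,
    n_seeds: int = 20,
    n_participants: int = 6,
    n_points: int = 25,
    max_epochs: int = 20,
) -> float:
    """Mean LOSO accuracy over label-shuffled replicates (chance-level check).

    The cohort carries a real effect, but the labels are permuted before
    training, destroying the feature-label association; held-out accuracy
    should therefore hover at the 50% binomial chance level.
    """
    cfg = DrillRunConfig(
        drill="sprint",
        n_participants=n_participants,
        effects=(EffectSpec(dof="knee_flexext", window=(40.0, 60.0), offset_deg=10.0),),
        noise_sd=2.0,
        n_points=n_points,
    )
    dataset, _, _ = run_drill(
        cfg, seed=seed, catalog=DEFAULT_CATALOG.subset(list(REDUCED_DOFS[:3]))
    )
    accs = []
    for r in range(n_seeds):
        rng = np.random.default_rng((seed + 77 * r) & 0x7FFFFFFF)
        y_shuf = rng.permutation(dataset.y)
        res = loso_evaluate(
            dataset.X,
            y_shuf,
            dataset.participants,
            seed=seed + r,
            clf_params={"max_epochs": max_epochs},
        )
        accs.append(res.mean_accuracy)
    return float(np.mean(accs))


def ttest_type1_rate(
    seed: int, n_replicates: int = 1000, n: int = 17, alpha: float = 0.05
) -> float:
    """Empirical type-I error of the paired t-test under a true null."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(3.0, 0.3, n)
        b = a + rng.normal(0.0, 0.1, n)  # paired, zero true shift
        if paired_t(a, b).p < alpha:
            rejections += 1
    return 100.0 * rejections / n_replicates
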
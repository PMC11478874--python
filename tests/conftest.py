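import numpy as np
import pytest

from kinelrp import DEFAULT_CATALOG, EffectSpec, SynthConfig, generate_cohort


REDUCED_DOFS = [
    "hip_flexext",
    "knee_flexext",
    "ankle_flexext",
    "shoulder_flexext",
    "shoulder_abdadd",
    "elbow_flexext",
]


@pytest.fixture(scope="session")
def reduced_catalog():
    return DEFAULT_CATALOG.subset(REDUCED_DOFS)


@pytest.fixture(scope="session")
def sprint_noiseless():
    """Two-participant noiseless sprint cohort with exact truth events."""
    cfg = SynthConfig(n_participants=2, drill="sprint", noise_sd=0.0, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def shot_noiseless():
    cfg = SynthConfig(n_participants=2, drill="slapshot", noise_sd=0.0, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def turn_noiseless():
    cfg = SynthConfig(n_participants=2, drill="powerturn", noise_sd=0.0, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort(reduced_catalog):
    """Small sprint cohort with a known 10-degree restriction injected into
    shoulder flexion/extension at 40-60% of the stride cycle."""
    cfg = SynthConfig(
        n_participants=6,
        drill="sprint",
        effects=(EffectSpec(dof="shoulder_flex" "ext", window=(40.0, 60.0), offset_deg=10.0),),
        participant_sd=2.0,
        noise_sd=1.0,
        seed=11,
        catalog=reduced_catalog,
    )
    return cfg, generate_cohort(cfg)


def angles_stack(trials, channel, condition):
    return np.stack(
        [t.joint_angles[channel] for t in trials if t.condition == condition]
    )
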
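"""Synthetic IMU kinematics with known ground truth.

Generates cohorts of trials that emulate on-ice drill recordings: periodic
multi-joint angle trajectories (sums of 1-3 harmonics) with participant-level
random effects, condition-specific restrictions injected into chosen DOFs and
phase windows, white sensor noise, and the auxiliary raw signals the
segmentation stage relies on (foot vertical velocity, pelvis vertical angular
velocity, shoulder angular velocity, hand vertical velocity) with exact
ground-truth event indices.

The generator is a test bed, not a biomechanical simulation: its purpose is
that every downstream stage (segmentation, feature construction,
classification, relevance attribution) can be validated against a known
injected truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, DOFCatalog, SIDES, channel_name

DRILLS = ("sprint", "crossover", "slapshot", "powerturn")

CONDITIONS = ("Equipment", "NoEquipment")

#: Per-drill defaults: seconds per movement cycle and number of cycles
#: (strides per foot / turns; the slap shot is a single movement).
DRILL_DEFAULTS: dict[str, tuple[float, int]] = {
    "sprint": (0.8, 6),
    "crossover": (1.0, 6),
    "slapshot": (1.5, 1),
    "powerturn": (4.0, 6),
}

#: Width of the cosine taper flanking an injected effect window, in % of cycle.
TAPER_PERCENT = 5.0

# Raw-signal waveform constants (m/s and rad/s; see docs/methods.md).
_CONTACT_DIP = 1.5       # depth of the ice-contact dip in foot vertical velocity
_SWING_BUMP = 0.9        # height of the swing-phase bump
_HAND_PEAK = 1.2         # peak hand vertical velocity during the shot
_SHOULDER_PEAK = 3.0     # peak shoulder angular velocity on the shooting side
_OFFSIDE_FRACTION = 0.25 # non-dominant side amplitude fraction
_TURN_PEAK = 2.0         # peak pelvis vertical angular velocity
_SHOT_LEAD_S = 2.0       # quiet lead-in before the shot
_SHOT_TAIL_S = 2.0       # follow-through + quiet tail after the strike


@dataclass(frozen=True)
class EffectSpec:
    """A condition-specific restriction injected into one DOF.

    Inside the phase window ``[a, b]`` (percent of cycle) Equipment-condition
    trajectories are transformed as ``x -> scale*x + offset_deg``, blended in
    with cosine tapers over ``TAPER_PERCENT`` of the cycle on either flank so
    the full effect holds on the window itself and fades smoothly outside it.
    ``side`` restricts the effect to one body side; None applies it to both,
    each at its own cycle phase.
    """

    dof: str
    window: tuple[float, float]
    offset_deg: float
    scale: float = 1.0
    side: str | None = None


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int
    drill: str
    trials_per_condition: int = 2
    sample_rate: float = 60.0
    cycle_duration: float | None = None
    n_cycles: int | None = None
    effects: tuple[EffectSpec, ...] = ()
    participant_sd: float = 2.0
    noise_sd: float = 1.0
    raw_noise_scale: float = 0.02  # raw-signal noise sd = raw_noise_scale * noise_sd
    shot_side: str = "R"
    seed: int = 0
    catalog: DOFCatalog = field(default_factory=lambda: DEFAULT_CATALOG)

    def __post_init__(self) -> None:
        if self.drill not in DRILLS:
            raise ValueError(f"unknown drill {self.drill!r}; expected one of {DRILLS}")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.noise_sd < 0 or self.participant_sd < 0:
            raise ValueError("noise_sd and participant_sd must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.shot_side not in SIDES:
            raise ValueError(f"shot_side must be one of {SIDES}")
        cyc, n = DRILL_DEFAULTS[self.drill]
        if self.cycle_duration is None:
            object.__setattr__(self, "cycle_duration", cyc)
        if self.n_cycles is None:
            object.__setattr__(self, "n_cycles", n)
        if self.cycle_duration <= 0 or self.n_cycles < 1:
            raise ValueError("cycle_duration must be > 0 and n_cycles >= 1")
        for eff in self.effects:
            a, b = eff.window
            if not (0.0 <= a < b <= 100.0):
                raise ValueError(f"effect window {eff.window} outside [0, 100]")
            if eff.dof not in self.catalog:
                raise ValueError(
                    f"effect targets DOF {eff.dof!r} not in the retained catalog "
                    f"(excluded or unknown)"
                )
            if eff.side is not None and eff.side not in SIDES:
                raise ValueError(f"effect side must be one of {SIDES} or None")


@dataclass
class TrialRecording:
    """One participant x drill x condition x trial at a fixed sample rate."""

    participant_id: str
    condition: str
    drill: str
    trial_index: int
    time: np.ndarray
    joint_angles: dict[str, np.ndarray]
    raw_signals: dict[str, np.ndarray]
    truth_events: dict[str, list]
    sample_rate: float

    @property
    def n_samples(self) -> int:
        return len(self.time)


def _dof_base_params(dof: str) -> dict[str, np.ndarray | float]:
    """Fixed harmonic parameters for one DOF, stable across seeds and cohorts."""
    rng = np.random.default_rng([0xD0F, zlib.crc32(dof.encode())])
    return {
        "offset": float(rng.uniform(-10.0, 30.0)),
        "amps": np.array(
            [rng.uniform(8.0, 20.0), rng.uniform(2.0, 6.0), rng.uniform(0.5, 2.0)]
        ),
        "phases": rng.uniform(0.0, 2.0 * np.pi, size=3),
    }


def _participant_modifiers(
    config: SynthConfig, p_index: int
) -> dict[str, dict[str, float]]:
    """Between-participant random effects: multiplicative on harmonic
    amplitudes, additive on baseline offsets (sd = participant_sd degrees)."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 1000 + p_index])
    mods: dict[str, dict[str, float]] = {}
    for side in SIDES:
        for dof in config.catalog.dofs:
            mods[channel_name(side, dof)] = {
                "amp_factor": float(np.exp(rng.normal(0.0, config.participant_sd / 20.0))),
                "offset_shift": float(rng.normal(0.0, config.participant_sd)),
            }
    return mods


def _taper_weight(phase_pct: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Plateau 1 on [a, b], cosine ramps over TAPER_PERCENT outside each edge."""
    a, b = window
    tau = TAPER_PERCENT
    w = np.zeros_like(phase_pct)
    w[(phase_pct >= a) & (phase_pct <= b)] = 1.0
    rise = (phase_pct >= a - tau) & (phase_pct < a)
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * (phase_pct[rise] - (a - tau)) / tau))
    fall = (phase_pct > b) & (phase_pct <= b + tau)
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (phase_pct[fall] - b) / tau))
    return w


def _trial_duration_s(config: SynthConfig) -> float:
    T, n = config.cycle_duration, config.n_cycles
    if config.drill in ("sprint", "crossover"):
        return (n + 1) * T
    if config.drill == "powerturn":
        return (n + 1) * T
    return _SHOT_LEAD_S + T + _SHOT_TAIL_S  # slapshot


def _side_phase(config: SynthConfig, t: np.ndarray, side: str) -> np.ndarray:
    """Movement-cycle phase in [0, 1) for one body side."""
    T = config.cycle_duration
    if config.drill in ("sprint", "crossover"):
        shift = 0.5 * T if side == "L" else T
        return ((t - shift) / T) % 1.0
    if config.drill == "powerturn":
        return ((t - 0.5 * T) / T) % 1.0
    # slapshot: single cycle between waveform start and strike, clamped outside
    return np.clip((t - _SHOT_LEAD_S) / T, 0.0, 1.0)


def _wrapped_gaussian(phase: np.ndarray, center: float, sigma: float) -> np.ndarray:
    d = np.abs(phase - center)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / sigma) ** 2)


def generate_raw_signals(trial: TrialRecording, config: SynthConfig) -> TrialRecording:
    """Populate a trial's segmentation signals and ground-truth event indices.

    Signals are built so that a perfect detector applying the documented
    segmentation rules to the noiseless versions recovers ``truth_events``
    exactly: sprint/crossover ice contacts are symmetric dips in foot vertical
    velocity centred on the truth samples; the power-turn pelvis angular
    velocity is a slow sinusoid whose sign changes are the turn boundaries;
    the slap-shot truth start/end are computed from the noiseless hand
    velocity with the same 5%-of-peak and post-peak sign-reversal rules the
    detector uses.
    """
    if trial.time is None or len(trial.time) == 0:
        raise ValueError("trial has no time axis")
    t = trial.time
    fs = trial.sample_rate
    T = config.cycle_duration
    n = len(t)
    p_index = int(trial.participant_id.lstrip("S")) - 1
    rng = np.random.default_rng(
        [
            config.seed & 0x7FFFFFFF,
            1000 + p_index,
            CONDITIONS.index(trial.condition),
            trial.trial_index,
            0x5A,
        ]
    )
    noise_sd = config.raw_noise_scale * config.noise_sd
    raw: dict[str, np.ndarray] = {}
    truth: dict[str, list] = {}

    def _noise(size: int) -> np.ndarray:
        return rng.normal(0.0, noise_sd, size) if noise_sd > 0 else np.zeros(size)

    if config.drill in ("sprint", "crossover"):
        for side in SIDES:
            phase = _side_phase(config, t, side)
            v = _SWING_BUMP * _wrapped_gaussian(phase, 0.5, 0.10)
            v -= _CONTACT_DIP * _wrapped_gaussian(phase, 0.0, 0.045)
            raw[f"foot_vert_velocity_{side}"] = v + _noise(n)
            shift = 0.5 * T if side == "L" else T
            contacts = []
            k = 0
            while True:
                idx = int(round((shift + k * T) * fs))
                if idx >= n:
                    break
                contacts.append(idx)
                k += 1
            truth[f"ice_contact_{side}"] = contacts
    elif config.drill == "powerturn":
        # Alternating-sign lobes, one per turn, with half-lobes at the
        # boundaries (the figure-eight begins and ends mid-turn).
        s = _TURN_PEAK * np.cos(np.pi * t / T)
        raw["pelvis_angvel_z"] = s + _noise(n)
        boundaries = []
        k = 0
        while True:
            idx = int(round((0.5 + k) * T * fs))
            if idx >= n:
                break
            boundaries.append(idx)
            k += 1
        truth["turn_boundary"] = boundaries
    else:  # slapshot
        dur = T
        u = (t - _SHOT_LEAD_S) / dur
        up = np.where((u >= 0.0) & (u <= 1.0), np.sin(np.pi * np.clip(u, 0, 1)), 0.0)
        u2 = (t - _SHOT_LEAD_S - dur) / (0.5 * dur)
        down = np.where(
            (u2 > 0.0) & (u2 <= 1.0), np.sin(np.pi * np.clip(u2, 0, 1)), 0.0
        )
        hand = _HAND_PEAK * up - 0.35 * _HAND_PEAK * down
        shoulder = _SHOULDER_PEAK * up
        dom, off = (
            ("R", "L") if config.shot_side == "R" else ("L", "R")
        )
        raw[f"hand_vert_velocity_{dom}"] = hand + _noise(n)
        raw[f"hand_vert_velocity_{off}"] = _OFFSIDE_FRACTION * hand + _noise(n)
        raw[f"shoulder_angvel_{dom}"] = shoulder + _noise(n)
        raw[f"shoulder_angvel_{off}"] = _OFFSIDE_FRACTION * shoulder + _noise(n)
        # Truth from the noiseless signal with the detector's own definitions.
        peak_idx = int(np.argmax(hand))
        thresh = 0.05 * hand[peak_idx]
        above = np.nonzero(hand[: peak_idx + 1] > thresh)[0]
        start = int(above[0]) - 1 if len(above) else 0
        after = np.nonzero(hand[peak_idx:] <= 0.0)[0]
        end = peak_idx + int(after[0]) if len(after) else n - 1
        truth["shot_start"] = [start]
        truth["shot_end"] = [end]
        truth["shot_side"] = [dom]

    trial.raw_signals = raw
    trial.truth_events = truth
    return trial


def _angle_channels(
    config: SynthConfig,
    t: np.ndarray,
    condition: str,
    mods: dict[str, dict[str, float]],
    rng_noise: np.random.Generator,
) -> dict[str, np.ndarray]:
    angles: dict[str, np.ndarray] = {}
    for side in SIDES:
        phase = _side_phase(config, t, side)
        for dof in config.catalog.dofs:
            ch = channel_name(side, dof)
            base = _dof_base_params(dof)
            m = mods[ch]
            x = np.full_like(t, base["offset"] + m["offset_shift"])
            for h in range(3):
                x += (
                    m["amp_factor"]
                    * base["amps"][h]
                    * np.sin(2.0 * np.pi * (h + 1) * phase + base["phases"][h])
                )
            if condition == "Equipment":
                pct = 100.0 * phase
                for eff in config.effects:
                    if eff.dof != dof or (eff.side is not None and eff.side != side):
                        continue
                    w = _taper_weight(pct, eff.window)
                    x = x + w * ((eff.scale - 1.0) * x + eff.offset_deg)
            if config.noise_sd > 0:
                x = x + rng_noise.normal(0.0, config.noise_sd, len(t))
            angles[ch] = x
    return angles


def generate_cohort(config: SynthConfig) -> list[TrialRecording]:
    """Generate all trials of a synthetic cohort.

    Per-participant random streams are derived from the global seed by fixed
    offsets, so adding participants to a config leaves the earlier
    participants' data bit-identical.
    """
    fs = config.sample_rate
    n_samples = int(round(_trial_duration_s(config) * fs))
    t = np.arange(n_samples) / fs
    trials: list[TrialRecording] = []
    for p in range(config.n_participants):
        pid = f"S{p + 1:02d}"
        mods = _participant_modifiers(config, p)
        for ci, condition in enumerate(CONDITIONS):
            for trial_idx in range(config.trials_per_condition):
                rng_noise = np.random.default_rng(
                    [config.seed & 0x7FFFFFFF, 1000 + p, ci, trial_idx, 0xA1]
                )
                trial = TrialRecording(
                    participant_id=pid,
                    condition=condition,
                    drill=config.drill,
                    trial_index=trial_idx,
                    time=t.copy(),
                    joint_angles=_angle_channels(config, t, condition, mods, rng_noise),
                    raw_signals={},
                    truth_events={},
                    sample_rate=fs,
                )
                generate_raw_signals(trial, config)
                trials.append(trial)
    return trials


# ---------------------------------------------------------------------------
# CSV / JSON interchange


def trial_to_frame(trial: TrialRecording) -> pd.DataFrame:
    cols: dict[str, object] = {
        "time_s": trial.time,
        "condition": trial.condition,
        "participant": trial.participant_id,
        "drill": trial.drill,
        "trial": trial.trial_index,
    }
    for ch, x in trial.joint_angles.items():
        cols[ch] = x
    for ch, x in trial.raw_signals.items():
        cols[f"raw_{ch}"] = x
    return pd.DataFrame(cols)


def trial_from_frame(df: pd.DataFrame, truth_events: dict | None = None) -> TrialRecording:
    meta_cols = {"time_s", "condition", "participant", "drill", "trial"}
    time = df["time_s"].to_numpy(float)
    if len(time) < 2:
        raise ValueError("trial frame must have >= 2 samples")
    fs = 1.0 / float(np.median(np.diff(time)))
    angles, raw = {}, {}
    for col in df.columns:
        if col in meta_cols:
            continue
        if col.startswith("raw_"):
            raw[col[4:]] = df[col].to_numpy(float)
        else:
            angles[col] = df[col].to_numpy(float)
    return TrialRecording(
        participant_id=str(df["participant"].iloc[0]),
        condition=str(df["condition"].iloc[0]),
        drill=str(df["drill"].iloc[0]),
        trial_index=int(df["trial"].iloc[0]),
        time=time,
        joint_angles=angles,
        raw_signals=raw,
        truth_events=truth_events or {},
        sample_rate=round(fs, 6),
    )


def write_cohort_csv(trials: list[TrialRecording], directory) -> list[str]:
    """One CSV per trial plus a sidecar JSON of ground-truth events."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    truth_records = []
    for tr in trials:
        name = f"{tr.drill}_{tr.participant_id}_{tr.condition}_t{tr.trial_index}.csv"
        trial_to_frame(tr).to_csv(directory / name, index=False)
        paths.append(str(directory / name))
        for event_type, indices in tr.truth_events.items():
            for idx in indices:
                truth_records.append(
                    {
                        "participant": tr.participant_id,
                        "condition": tr.condition,
                        "trial": tr.trial_index,
                        "event": event_type,
                        "index": idx if isinstance(idx, str) else int(idx),
                    }
                )
    with open(directory / "truth_events.json", "w") as fh:
        json.dump(truth_records, fh, indent=1)
    return paths


def read_trial_csv(path, truth_events: dict | None = None) -> TrialRecording:
    return trial_from_frame(pd.read_csv(path), truth_events)
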
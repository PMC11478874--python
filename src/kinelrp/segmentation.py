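"""Drill-specific movement extraction from raw IMU signals.

Each drill has its own rule set, all built on zero-lag low-pass Butterworth
filtering of one or two auxiliary signals:

* sprint / linear crossover — ice contacts of each skate are detected as
  sharp local minima of the low-pass filtered (4th order, 5 Hz) vertical
  foot velocity; a stride (or crossover) is the interval between two
  consecutive contacts of the same foot.
* slap shot — the shooting side is the shoulder with the larger peak
  filtered (4 Hz) vertical angular velocity; the shot runs from the start
  of the hand's vertical-velocity deflection to the post-peak sign reversal
  (puck-strike proxy).
* power turn — the circuit is split at every sign change of the heavily
  filtered (0.5 Hz) pelvis vertical angular velocity; each interior segment
  is one turn, labelled by the sign of the filtered signal within it.

Indices are 0-based; segments are half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, lfilter


class SegmentationError(Exception):
    """Base class for extraction failures."""


class TrialExclusionError(SegmentationError):
    """The required number of movements could not be extracted from a trial
    (the per-trial exclusion signal; the caller decides whether it is fatal)."""


@dataclass(frozen=True)
class FilterSpec:
    cutoff: float
    sample_rate: float
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < self.sample_rate / 2.0):
            raise ValueError(
                f"cutoff must lie in (0, Nyquist={self.sample_rate / 2}); got {self.cutoff}"
            )
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")


def sprint_filter(fs: float = 60.0) -> FilterSpec:
    return FilterSpec(cutoff=5.0, sample_rate=fs)


def shot_filter(fs: float = 60.0) -> FilterSpec:
    return FilterSpec(cutoff=4.0, sample_rate=fs)


def turn_filter(fs: float = 60.0) -> FilterSpec:
    return FilterSpec(cutoff=0.5, sample_rate=fs)


@dataclass(frozen=True)
class MovementSegment:
    segment_type: str          # stride | crossover | shot | turn
    side_or_direction: str     # left | right | clockwise | counterclockwise | dominant
    start_idx: int
    end_idx: int
    participant_id: str = ""
    drill: str = ""
    condition: str = ""
    source_trial: int = -1

    def __post_init__(self) -> None:
        if self.start_idx >= self.end_idx:
            raise ValueError(
                f"empty segment: start {self.start_idx} >= end {self.end_idx}"
            )

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx


def lowpass_zero_lag(signal: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Low-pass Butterworth filter, applied forward-backward when zero_lag.

    The forward-backward application doubles the effective attenuation
    (squared magnitude response) and cancels the phase shift, the standard
    biomechanics convention for "zero-lag" filtering.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if len(x) <= 3 * spec.order:
        raise ValueError(
            f"signal length {len(x)} too short for order-{spec.order} filtering "
            f"(need > {3 * spec.order} samples)"
        )
    b, a = butter(spec.order, spec.cutoff, btype="low", fs=spec.sample_rate)
    if spec.zero_lag:
        return filtfilt(b, a, x)
    return lfilter(b, a, x)


def detect_ice_contacts(
    foot_vert_velocity: np.ndarray,
    spec: FilterSpec,
    min_separation_s: float = 0.3,
    prominence_frac: float = 0.2,
) -> list[int]:
    """Ice contacts: sharp local minima of the filtered vertical foot velocity.

    A contact is a local minimum that is negative (the skate decelerates into
    the ice and the velocity rises back toward zero), with prominence at
    least ``prominence_frac`` of the filtered signal's peak-to-peak range,
    and separated from other contacts by ``min_separation_s``.  Returns an
    empty list when no contacts are found.
    """
    f = lowpass_zero_lag(foot_vert_velocity, spec)
    ptp = float(np.ptp(f))
    if ptp <= 0.0:
        return []
    distance = max(1, int(round(min_separation_s * spec.sample_rate)))
    peaks, _ = find_peaks(-f, distance=distance, prominence=prominence_frac * ptp)
    return [int(p) for p in peaks if f[p] < 0.0]


def extract_strides(
    contacts_left: list[int],
    contacts_right: list[int],
    n_per_foot: int,
    segment_type: str = "stride",
    **meta,
) -> list[MovementSegment]:
    """Contact-to-next-same-foot-contact intervals, ``n_per_foot`` per foot."""
    segments: list[MovementSegment] = []
    for side_name, contacts in (("left", contacts_left), ("right", contacts_right)):
        if len(contacts) < n_per_foot + 1:
            raise TrialExclusionError(
                f"{side_name} foot has {len(contacts)} contacts; "
                f"{n_per_foot + 1} needed for {n_per_foot} {segment_type}s"
            )
        for k in range(n_per_foot):
            segments.append(
                MovementSegment(
                    segment_type=segment_type,
                    side_or_direction=side_name,
                    start_idx=int(contacts[k]),
                    end_idx=int(contacts[k + 1]),
                    **meta,
                )
            )
    return segments


def detect_shot(
    shoulder_angvel_L: np.ndarray,
    shoulder_angvel_R: np.ndarray,
    hand_vert_velocity_L: np.ndarray,
    hand_vert_velocity_R: np.ndarray,
    spec: FilterSpec,
    start_frac: float = 0.05,
    **meta,
) -> MovementSegment:
    """Extract the single shot of a shooting trial.

    The shot side is the shoulder with the larger peak absolute filtered
    angular velocity.  Start: searching backward from the hand-velocity peak,
    the last sample at which the deflection is below ``start_frac`` of the
    peak.  End: the first post-peak sample at which the hand velocity
    reverses sign (the stick hitting the puck stops the hand).
    """
    f_sh = {
        "left": lowpass_zero_lag(shoulder_angvel_L, spec),
        "right": lowpass_zero_lag(shoulder_angvel_R, spec),
    }
    peak_l = float(np.max(np.abs(f_sh["left"])))
    peak_r = float(np.max(np.abs(f_sh["right"])))
    if peak_l == 0.0 and peak_r == 0.0:
        raise SegmentationError("no shoulder deflection; cannot determine shot side")
    side = "right" if peak_r >= peak_l else "left"
    lo, hi = sorted([peak_l, peak_r])
    if lo > 0 and (hi - lo) / hi < 0.05:
        warnings.warn(
            "ambiguous shot side: shoulder peaks within 5%; choosing the larger",
            stacklevel=2,
        )
    hand = hand_vert_velocity_R if side == "right" else hand_vert_velocity_L
    f_hand = lowpass_zero_lag(hand, spec)
    peak_idx = int(np.argmax(np.abs(f_hand)))
    peak_val = f_hand[peak_idx]
    if peak_val == 0.0:
        raise SegmentationError("no hand deflection; shot extraction failed")
    s = f_hand * np.sign(peak_val)  # orient the deflection positive
    thresh = start_frac * s[peak_idx]
    below = np.nonzero(s[: peak_idx + 1] < thresh)[0]
    if len(below) == 0:
        raise SegmentationError("hand deflection has no quiescent start")
    start = int(below[-1])
    after = np.nonzero(s[peak_idx:] <= 0.0)[0]
    end = peak_idx + int(after[0]) if len(after) else len(s) - 1
    if end <= start:
        raise SegmentationError("degenerate shot boundaries")
    return MovementSegment(
        segment_type="shot",
        side_or_direction=side,
        start_idx=start,
        end_idx=end,
        **meta,
    )


def split_turns(
    pelvis_angvel_z: np.ndarray,
    spec: FilterSpec,
    n_turns: int,
    **meta,
) -> list[MovementSegment]:
    """Split a power-turn circuit at sign changes of the filtered pelvis
    vertical angular velocity.  The first and last (partial) segments are
    discarded; each remaining segment is one turn, labelled clockwise when
    the filtered signal is negative within it and counterclockwise when
    positive."""
    f = lowpass_zero_lag(pelvis_angvel_z, spec)
    sign = np.sign(f)
    sign[sign == 0] = 1
    crossings = np.nonzero(np.diff(sign) != 0)[0] + 1
    if len(crossings) < 2:
        raise TrialExclusionError(
            f"only {len(crossings)} sign changes; no complete turn to extract"
        )
    bounds = list(crossings)  # interior segments are between consecutive crossings
    segments: list[MovementSegment] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        mean_sign = np.sign(np.mean(f[s:e]))
        direction = "counterclockwise" if mean_sign > 0 else "clockwise"
        segments.append(
            MovementSegment(
                segment_type="turn",
                side_or_direction=direction,
                start_idx=int(s),
                end_idx=int(e),
                **meta,
            )
        )
    if len(segments) < n_turns:
        raise TrialExclusionError(
            f"{len(segments)} complete turns found; {n_turns} required"
        )
    return segments[:n_turns]


def segment_trial(trial, n_per_foot: int | None = None, n_turns: int = 6) -> list[MovementSegment]:
    """Apply the drill-appropriate extraction rule to one trial."""
    fs = trial.sample_rate
    meta = dict(
        participant_id=trial.participant_id,
        drill=trial.drill,
        condition=trial.condition,
        source_trial=trial.trial_index,
    )
    if trial.drill in ("sprint", "crossover"):
        if n_per_foot is None:
            n_per_foot = 3 if trial.drill == "sprint" else 1
        spec = sprint_filter(fs)
        contacts = {
            side: detect_ice_contacts(trial.raw_signals[f"foot_vert_velocity_{side}"], spec)
            for side in ("L", "R")
        }
        seg_type = "stride" if trial.drill == "sprint" else "crossover"
        return extract_strides(
            contacts["L"], contacts["R"], n_per_foot, segment_type=seg_type, **meta
        )
    if trial.drill == "slapshot":
        spec = shot_filter(fs)
        return [
            detect_shot(
                trial.raw_signals["shoulder_angvel_L"],
                trial.raw_signals["shoulder_angvel_R"],
                trial.raw_signals["hand_vert_velocity_L"],
                trial.raw_signals["hand_vert_velocity_R"],
                spec,
                **meta,
            )
        ]
    if trial.drill == "powerturn":
        return split_turns(
            trial.raw_signals["pelvis_angvel_z"], turn_filter(fs), n_turns, **meta
        )
    raise ValueError(f"unknown drill {trial.drill!r}")
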
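"""Feature construction: time normalization, ratio-preserving scaling,
and concatenation into fixed-length vectors.

Every extracted movement is time-normalized to 100 cycle points by cubic
spline interpolation, scaled participant-wise into [-1, 1] while preserving
the relative magnitude between joints through a pre-set range-of-motion
ratio table, and the per-DOF trajectories are concatenated into a single
feature vector: 12 x 100 = 1200 values for the (symmetric, unilateral)
sprint, 24 x 100 = 2400 values for the bilateral drills.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .catalog import ChannelMap, DOFCatalog, DEFAULT_CATALOG
from .segmentation import MovementSegment


def resample_to_cycle(traj: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Time-normalize one trajectory to ``n_points`` cycle fractions.

    A cubic spline through all input samples (uniform grid on [0, 1]) is
    evaluated at ``n_points`` equally spaced fractions; endpoints are
    reproduced exactly, and a trajectory already of length ``n_points`` on a
    uniform grid is returned unchanged (evaluation at the knots).
    """
    y = np.asarray(traj, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError(
            f"trajectory must be 1-D with >= 4 samples for cubic interpolation; got length {y.shape}"
        )
    x = np.linspace(0.0, 1.0, len(y))
    return CubicSpline(x, y)(np.linspace(0.0, 1.0, n_points))


@dataclass
class SegmentTrajectories:
    """Resampled (but not yet normalized) trajectories of one movement,
    keyed by feature-vector block label (DOF name, or ipsi_/contra_ DOF)."""

    segment: MovementSegment
    trajectories: dict[str, np.ndarray]

    @property
    def participant_id(self) -> str:
        return self.segment.participant_id

    @property
    def condition(self) -> str:
        return self.segment.condition


def extract_segment_trajectories(
    trial,
    segment: MovementSegment,
    catalog: DOFCatalog = DEFAULT_CATALOG,
    bilateral: bool = True,
    n_points: int = 100,
) -> SegmentTrajectories:
    """Slice one movement out of a trial and time-normalize each channel.

    Unilateral layouts keep only the movement's own (ipsilateral) side and
    key blocks by bare DOF name.  Bilateral layouts put the ipsilateral side
    first, then the contralateral side.  For shots the ipsilateral side is
    the shooting side; for turns it is the inside-facing side (right for a
    clockwise turn).
    """
    ipsi = {"left": "L", "right": "R", "clockwise": "R", "counterclockwise": "L"}.get(
        segment.side_or_direction, "R"
    )
    contra = "L" if ipsi == "R" else "R"
    if segment.end_idx > trial.n_samples:
        raise ValueError("segment extends past the end of the trial")
    sl = slice(segment.start_idx, segment.end_idx)
    trajs: dict[str, np.ndarray] = {}
    missing = []
    for dof in catalog.dofs:
        key_i = f"{ipsi}_{dof}"
        if key_i not in trial.joint_angles:
            missing.append(key_i)
            continue
        label = dof if not bilateral else f"ipsi_{dof}"
        trajs[label] = resample_to_cycle(trial.joint_angles[key_i][sl], n_points)
        if bilateral:
            key_c = f"{contra}_{dof}"
            if key_c not in trial.joint_angles:
                missing.append(key_c)
                continue
            trajs[f"contra_{dof}"] = resample_to_cycle(
                trial.joint_angles[key_c][sl], n_points
            )
    if missing:
        raise KeyError(f"trial lacks required angle channels: {missing}")
    return SegmentTrajectories(segment=segment, trajectories=trajs)


def normalize_participant(
    segments: list[SegmentTrajectories],
    ratios: dict[str, float],
    channel_map: ChannelMap,
) -> tuple[list[SegmentTrajectories], dict[str, float]]:
    """Ratio-preserving participant-wise normalization.

    For each block label ``d``:  ``x_norm = ratio(d) * x / max_abs(d)`` where
    ``max_abs(d)`` is the maximum absolute angle over *all* of the
    participant's segments and both conditions.  Pooling over conditions is
    deliberate: per-condition scaling would leak the class label into the
    features.  Returns normalized copies plus the scaling constants for audit.
    """
    pids = {s.participant_id for s in segments}
    if len(pids) != 1:
        raise ValueError(f"normalize_participant expects one participant, got {pids}")
    max_abs: dict[str, float] = {b: 0.0 for b in channel_map.blocks}
    for seg in segments:
        for block, x in seg.trajectories.items():
            max_abs[block] = max(max_abs[block], float(np.max(np.abs(x))))
    out: list[SegmentTrajectories] = []
    for seg in segments:
        normed = {}
        for block, x in seg.trajectories.items():
            r = ratios[channel_map.base_dof(block)]
            if max_abs[block] == 0.0:
                warnings.warn(
                    f"block {block} is identically zero for participant "
                    f"{seg.participant_id}; normalized output set to zeros",
                    stacklevel=2,
                )
                normed[block] = np.zeros_like(x)
            else:
                normed[block] = r * x / max_abs[block]
        out.append(SegmentTrajectories(segment=seg.segment, trajectories=normed))
    return out, max_abs


@dataclass
class FeatureVector:
    values: np.ndarray
    channel_map: ChannelMap
    label: str
    participant_id: str
    segment: MovementSegment | None = None


def build_feature_vector(
    seg: SegmentTrajectories, channel_map: ChannelMap
) -> FeatureVector:
    """Concatenate a segment's normalized trajectories in catalog block order."""
    missing = [b for b in channel_map.blocks if b not in seg.trajectories]
    if missing:
        raise KeyError(f"missing channels for feature vector: {missing}")
    values = np.concatenate([seg.trajectories[b] for b in channel_map.blocks])
    return FeatureVector(
        values=values,
        channel_map=channel_map,
        label=seg.condition,
        participant_id=seg.participant_id,
        segment=seg.segment,
    )


@dataclass
class FeatureDataset:
    """Design matrix plus bookkeeping for one drill's cohort."""

    X: np.ndarray             # (n_segments, n_features)
    y: np.ndarray             # condition labels (str)
    participants: np.ndarray  # participant id per row (str)
    channel_map: ChannelMap
    scales: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{b}_{t:03d}"
            for b in self.channel_map.blocks
            for t in range(self.channel_map.n_points)
        ]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "participant", self.participants)
        df.insert(1, "condition", self.y)
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame, n_points: int) -> "FeatureDataset":
        feat_cols = [c for c in df.columns if c not in ("participant", "condition")]
        blocks = tuple(dict.fromkeys(c[: -4] for c in feat_cols))
        return FeatureDataset(
            X=df[feat_cols].to_numpy(float),
            y=df["condition"].to_numpy(str),
            participants=df["participant"].to_numpy(str),
            channel_map=ChannelMap(blocks=blocks, n_points=n_points),
        )


def featurize_cohort(
    trials,
    segments_by_trial: dict[int, list[MovementSegment]],
    catalog: DOFCatalog = DEFAULT_CATALOG,
    bilateral: bool = True,
    n_points: int = 100,
    ratios: dict[str, float] | None = None,
) -> FeatureDataset:
    """Full feature stage for a cohort: slice, resample, normalize, concatenate.

    ``segments_by_trial`` maps the index of each trial in ``trials`` to its
    extracted movements.  Normalization pools each participant's segments
    across both conditions.
    """
    ratio_table = catalog.ratios(ratios)
    channel_map = (
        ChannelMap.bilateral(catalog, n_points)
        if bilateral
        else ChannelMap.unilateral(catalog, n_points)
    )
    by_participant: dict[str, list[SegmentTrajectories]] = {}
    for ti, segs in segments_by_trial.items():
        trial = trials[ti]
        for seg in segs:
            st = extract_segment_trajectories(trial, seg, catalog, bilateral, n_points)
            by_participant.setdefault(trial.participant_id, []).append(st)
    rows, labels, pids = [], [], []
    scales: dict[str, dict[str, float]] = {}
    for pid in sorted(by_participant):
        normed, max_abs = normalize_participant(
            by_participant[pid], ratio_table, channel_map
        )
        scales[pid] = max_abs
        for seg in normed:
            fv = build_feature_vector(seg, channel_map)
            rows.append(fv.values)
            labels.append(fv.label)
            pids.append(pid)
    if not rows:
        raise ValueError("no segments to featurize")
    return FeatureDataset(
        X=np.vstack(rows),
        y=np.array(labels),
        participants=np.array(pids),
        channel_map=channel_map,
        scales=scales,
    )


def flag_unreliable_dofs(
    dataset: FeatureDataset, raw_by_participant: dict | None = None, threshold_deg: float = 1.0
) -> list[str]:
    """Report blocks whose between-condition mean-trajectory difference never
    exceeds the measurement system's ~1 degree accuracy (computed on raw,
    pre-normalization trajectories when provided).

    This mirrors the reliability screen that motivates the fixed exclusion
    list; it reports rather than drops, because the retained catalog is fixed.
    """
    flagged = []
    if raw_by_participant is not None:
        # raw_by_participant: pid -> list[SegmentTrajectories] (unnormalized)
        all_segs = [s for segs in raw_by_participant.values() for s in segs]
        blocks = dataset.channel_map.blocks
        for b in blocks:
            means = {}
            for cond in ("Equipment", "NoEquipment"):
                arrs = [s.trajectories[b] for s in all_segs if s.condition == cond]
                if arrs:
                    means[cond] = np.mean(arrs, axis=0)
            if len(means) == 2:
                diff = float(np.max(np.abs(means["Equipment"] - means["NoEquipment"])))
                if diff < threshold_deg:
                    flagged.append(b)
    return flagged
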
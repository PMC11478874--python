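"""Layer-wise relevance propagation and relevance-map aggregation.

Relevance is propagated from the pre-softmax score of the true class of a
correctly classified movement back to the 1200/2400 inputs with the
epsilon-stabilized z-rule:

    R_j = sum_k  (a_j w_jk) / (z_k + eps * sign(z_k)) * R_k,
    z_k = sum_j a_j w_jk + b_k.

Bias relevance is absorbed (not redistributed), the standard toolbox
behaviour; with zero biases the rule conserves relevance exactly, i.e. the
input relevances sum to the explained output score.

Each per-movement relevance pattern is then smoothed within every DOF's
100-point block with the kernel (0.25, 0.5, 0.25) applied twice (the current
point keeps 50% of its relevance, each neighbour receives 25%; the weights
sum to 1, so repeated application mimics a Gaussian filter).  Per
participant, smoothed patterns of the correctly classified movements are
averaged and L1-normalized; the cohort map is the participant average,
min-max rescaled to [0, 1], from which the marginal profiles (column sums
over time, row sums over DOFs) are taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ChannelMap
from .mlp import EvaluationResult, ShallowTanhClassifier

SMOOTH_KERNEL = np.array([0.25, 0.5, 0.25])


def lrp_epsilon(
    model: ShallowTanhClassifier,
    x: np.ndarray,
    target_class,
    epsilon: float = 1e-9,
) -> np.ndarray:
    """Input relevances for one movement, epsilon-stabilized z-rule.

    ``target_class`` may be a class label or an output index; relevance is
    initialized at that output's pre-softmax score.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_features_in_:
        raise ValueError(
            f"input length {x.shape[0]} != model input dim {model.n_features_in_}"
        )
    W1, W2 = model.coefs_
    b1, b2 = model.intercepts_
    z1 = x @ W1 + b1
    a1 = np.tanh(z1)
    z2 = a1 @ W2 + b2
    if isinstance(target_class, (int, np.integer)):
        k = int(target_class)
    else:
        k = int(np.nonzero(model.classes_ == target_class)[0][0])

    def _stab(z: np.ndarray) -> np.ndarray:
        s = np.where(z >= 0.0, 1.0, -1.0)
        denom = z + epsilon * s
        if np.any(denom == 0.0):
            raise ZeroDivisionError(
                "zero pre-activation with epsilon=0; increase epsilon"
            )
        return denom

    # output layer -> hidden layer
    R2 = np.zeros_like(z2)
    R2[k] = z2[k]
    R1 = a1 * (W2 @ (R2 / _stab(z2)))
    # hidden layer -> input layer
    R0 = x * (W1 @ (R1 / _stab(z1)))
    return R0


class LRPExplainer:
    """Convenience wrapper binding a fitted classifier to the epsilon rule."""

    def __init__(self, model: ShallowTanhClassifier, epsilon: float = 1e-9):
        self.model = model
        self.epsilon = epsilon

    def relevance(self, x: np.ndarray, target_class) -> np.ndarray:
        return lrp_epsilon(self.model, x, target_class, self.epsilon)


def smooth_relevance(
    R: np.ndarray, n_points: int = 100, passes: int = 2
) -> np.ndarray:
    """Smooth a relevance vector within each DOF block independently.

    The (0.25, 0.5, 0.25) kernel is applied ``passes`` times per block with
    edge-value replication; blocks never mix, so relevance cannot leak from
    one DOF's trajectory into the next.
    """
    R = np.asarray(R, dtype=float).ravel()
    if len(R) % n_points:
        raise ValueError(f"vector length {len(R)} is not a multiple of {n_points}")
    out = R.reshape(-1, n_points).copy()
    for _ in range(passes):
        padded = np.pad(out, ((0, 0), (1, 1)), mode="edge")
        out = (
            SMOOTH_KERNEL[0] * padded[:, :-2]
            + SMOOTH_KERNEL[1] * padded[:, 1:-1]
            + SMOOTH_KERNEL[2] * padded[:, 2:]
        )
    return out.ravel()


@dataclass
class RelevanceMap:
    matrix: np.ndarray            # n_blocks x n_points
    blocks: tuple[str, ...]
    stage: str                    # raw | smoothed | participant_normalized | cohort_rescaled
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=list(self.blocks),
            columns=[f"pct_{t}" for t in range(self.matrix.shape[1])],
        )


@dataclass
class MarginalProfiles:
    time_profile: np.ndarray  # per cycle point, summed over DOFs
    dof_profile: np.ndarray   # per DOF, summed over time


def aggregate_participant(relevances: list[np.ndarray]) -> np.ndarray:
    """Mean over a participant's correctly classified movements, then
    L1-normalized so every participant contributes equally to the cohort."""
    if not relevances:
        raise ValueError("participant has no correctly classified segments")
    m = np.mean(relevances, axis=0)
    norm = float(np.sum(np.abs(m)))
    if norm == 0.0:
        raise ValueError("all-zero relevance; cannot normalize")
    return m / norm


def aggregate_cohort(
    participant_maps: list[np.ndarray], channel_map: ChannelMap
) -> tuple[RelevanceMap, MarginalProfiles]:
    """Average participant-normalized maps, min-max rescale to [0, 1], and
    compute the marginal profiles of the rescaled map."""
    if len(participant_maps) < 2:
        raise ValueError("cohort aggregation needs >= 2 participants")
    mean_vec = np.mean(participant_maps, axis=0)
    mat = mean_vec.reshape(channel_map.n_blocks, channel_map.n_points)
    lo, hi = float(mat.min()), float(mat.max())
    if hi == lo:
        raise ValueError("constant averaged map; min-max rescale undefined")
    rescaled = (mat - lo) / (hi - lo)
    profiles = MarginalProfiles(
        time_profile=rescaled.sum(axis=0), dof_profile=rescaled.sum(axis=1)
    )
    rmap = RelevanceMap(
        matrix=rescaled,
        blocks=channel_map.blocks,
        stage="cohort_rescaled",
        provenance={"n_participants": len(participant_maps)},
    )
    return rmap, profiles


def cohort_relevance_from_loso(
    result: EvaluationResult,
    X: np.ndarray,
    y: np.ndarray,
    channel_map: ChannelMap,
    epsilon: float = 1e-9,
    smoothing_passes: int = 2,
) -> tuple[RelevanceMap, MarginalProfiles]:
    """End-to-end relevance stage on a completed LOSO evaluation.

    For every participant, LRP (true-class score) is applied to their
    correctly classified held-out movements under that fold's model; each
    pattern is smoothed, the participant mean is L1-normalized, and the
    normalized maps are averaged across the cohort and rescaled to [0, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    participant_maps = []
    for pid, fold in result.folds.items():
        idx = fold.test_indices
        correct = idx[fold.predictions == y[idx]]
        if len(correct) == 0:
            warnings.warn(
                f"participant {pid}: no correctly classified segments; omitted",
                stacklevel=2,
            )
            continue
        rels = []
        for i in correct:
            r = lrp_epsilon(fold.model, X[i], y[i], epsilon)
            rels.append(smooth_relevance(r, channel_map.n_points, smoothing_passes))
        participant_maps.append(aggregate_participant(rels))
    rmap, profiles = aggregate_cohort(participant_maps, channel_map)
    rmap.provenance.update({"epsilon": epsilon, "smoothing_passes": smoothing_passes})
    return rmap, profiles
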
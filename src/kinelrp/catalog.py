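"""Degree-of-freedom catalog and range-of-motion normalization ratios.

The motion-capture export provides 3D joint angles for ankle, knee, hip,
shoulder, elbow and wrist, following the rotation-order convention
Z (flexion/extension), X (abduction/adduction), Y (internal/external
rotation); the elbow and wrist use pronation/supination in place of the
Y rotation.  Channels whose between-condition differences fall below the
system's ~1 degree accuracy are excluded up front: the whole wrist, ankle
abduction/adduction and knee abduction/adduction.  That leaves 12 retained
degrees of freedom per body side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Retained DOFs, proximal-to-distal within the lower then the upper extremity.
DOF_ORDER: tuple[str, ...] = (
    "hip_flexext",
    "hip_abdadd",
    "hip_introt",
    "knee_flexext",
    "knee_introt",
    "ankle_flexext",
    "ankle_introt",
    "shoulder_flexext",
    "shoulder_abdadd",
    "shoulder_introt",
    "elbow_flexext",
    "elbow_pronsup",
)

EXCLUDED_DOFS: tuple[str, ...] = (
    "wrist_flexext",
    "wrist_abdadd",
    "wrist_pronsup",
    "ankle_abdadd",
    "knee_abdadd",
)

SIDES: tuple[str, str] = ("L", "R")

#: Per-DOF normalization ratios relative to the overall maximum range of
#: motion (shoulder abduction/adduction, ratio 1).  These defaults are
#: derived from standard goniometry tables and are fully user-overridable;
#: they are generic reference values, not measurements from any one cohort.
DEFAULT_ROM_RATIOS: dict[str, float] = {
    "hip_flexext": 0.65,
    "hip_abdadd": 0.33,
    "hip_introt": 0.39,
    "knee_flexext": 0.61,
    "knee_introt": 0.13,
    "ankle_flexext": 0.30,
    "ankle_introt": 0.22,
    "shoulder_flexext": 0.96,
    "shoulder_abdadd": 1.00,
    "shoulder_introt": 0.78,
    "elbow_flexext": 0.65,
    "elbow_pronsup": 0.74,
}

REFERENCE_DOF = "shoulder_abdadd"


def channel_name(side: str, dof: str) -> str:
    """Canonical channel naming contract: ``side_joint_dof`` (e.g. R_knee_flexext)."""
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    return f"{side}_{dof}"


def split_channel(channel: str) -> tuple[str, str]:
    side, _, dof = channel.partition("_")
    if side not in SIDES or not dof:
        raise ValueError(f"malformed channel name {channel!r}")
    return side, dof


@dataclass(frozen=True)
class DOFCatalog:
    """Ordered set of retained degrees of freedom used to lay out feature vectors.

    The default catalog retains 12 DOFs per side.  Reduced catalogs (subsets)
    are used for scaled-down simulation studies; the ordering of `dofs` fixes
    the block order of every feature vector and relevance map built from it.
    """

    dofs: tuple[str, ...] = DOF_ORDER
    excluded: tuple[str, ...] = EXCLUDED_DOFS

    def __post_init__(self) -> None:
        if len(set(self.dofs)) != len(self.dofs):
            raise ValueError("duplicate DOFs in catalog")
        overlap = set(self.dofs) & set(self.excluded)
        if overlap:
            raise ValueError(f"DOFs both retained and excluded: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.dofs)

    def __contains__(self, dof: str) -> bool:
        return dof in self.dofs

    def subset(self, dofs: list[str] | tuple[str, ...]) -> "DOFCatalog":
        missing = [d for d in dofs if d not in self.dofs]
        if missing:
            raise ValueError(f"not in catalog: {missing}")
        return DOFCatalog(dofs=tuple(dofs), excluded=self.excluded)

    def ratios(self, table: dict[str, float] | None = None) -> dict[str, float]:
        """ROM ratio table restricted to this catalog (validated)."""
        table = dict(DEFAULT_ROM_RATIOS if table is None else table)
        missing = [d for d in self.dofs if d not in table]
        if missing:
            raise ValueError(f"ratio table missing DOFs: {missing}")
        for d in self.dofs:
            if not (0.0 < table[d] <= 1.0):
                raise ValueError(f"ratio for {d} must be in (0, 1], got {table[d]}")
        return {d: table[d] for d in self.dofs}


DEFAULT_CATALOG = DOFCatalog()


@dataclass(frozen=True)
class ChannelMap:
    """Bijection between feature-vector positions and (block, time point).

    A feature vector is a concatenation of contiguous ``n_points``-long
    blocks, one per channel, in the order given by ``blocks``.  For
    unilateral layouts the block labels are plain DOF names; for bilateral
    layouts they are ``ipsi_<dof>`` for the movement's own side followed by
    ``contra_<dof>`` for the opposite side (side-major ordering).
    """

    blocks: tuple[str, ...]
    n_points: int = 100

    def __len__(self) -> int:
        return len(self.blocks) * self.n_points

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def position(self, block: str, t: int) -> int:
        if not (0 <= t < self.n_points):
            raise IndexError(f"time point {t} outside [0, {self.n_points})")
        return self.blocks.index(block) * self.n_points + t

    def channel_at(self, pos: int) -> tuple[str, int]:
        if not (0 <= pos < len(self)):
            raise IndexError(f"position {pos} outside vector of length {len(self)}")
        b, t = divmod(pos, self.n_points)
        return self.blocks[b], t

    def block_slice(self, block: str) -> slice:
        i = self.blocks.index(block)
        return slice(i * self.n_points, (i + 1) * self.n_points)

    @staticmethod
    def unilateral(catalog: DOFCatalog, n_points: int = 100) -> "ChannelMap":
        return ChannelMap(blocks=tuple(catalog.dofs), n_points=n_points)

    @staticmethod
    def bilateral(catalog: DOFCatalog, n_points: int = 100) -> "ChannelMap":
        blocks = tuple(f"ipsi_{d}" for d in catalog.dofs) + tuple(
            f"contra_{d}" for d in catalog.dofs
        )
        return ChannelMap(blocks=blocks, n_points=n_points)

    def base_dof(self, block: str) -> str:
        for prefix in ("ipsi_", "contra_"):
            if block.startswith(prefix):
                return block[len(prefix):]
        return block
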
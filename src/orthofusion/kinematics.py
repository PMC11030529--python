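"""Pose-track error metrics: quaternion orientation error, position error,
NCC error, and per-trial summaries.

Rigid poses are unit quaternions (scalar-first, ``q`` and ``-q``
equivalent) plus translations in mm.  The orientation error between two
rotations p, q is the geodesic distance

    2 * arccos(|<p, q>|),   <p, q> = p1 q1 + p2 q2 + p3 q3 + p4 q4,

reported in degrees; the absolute value handles the double cover.  The
position error is the Euclidean distance between translations.  Tracking
quality of a shape-matched case is normalized frame by frame against the
reference track's correlation: NCC_error = (NCC_case - NCC_ref) / NCC_ref.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UnitQuaternion",
    "Pose",
    "PoseTrack",
    "TrialErrorSummary",
    "orientation_error",
    "position_error",
    "ncc_error",
    "relative_pose",
    "summarize_trial",
    "read_pose_tracks",
    "write_pose_tracks",
    "read_ncc_series",
]


class UnitQuaternion:
    """Scalar-first unit quaternion; normalized on construction."""

    __slots__ = ("q",)

    def __init__(self, w: float, x: float, y: float, z: float):
        q = np.array([w, x, y, z], dtype=float)
        n = np.linalg.norm(q)
        if n < 1e-12:
            raise ValueError("zero-norm quaternion")
        self.q = q / n

    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float) -> "UnitQuaternion":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        half = math.radians(angle_deg) / 2.0
        return cls(math.cos(half), *(math.sin(half) * axis))

    def conjugate(self) -> "UnitQuaternion":
        w, x, y, z = self.q
        return UnitQuaternion(w, -x, -y, -z)

    def __mul__(self, other: "UnitQuaternion") -> "UnitQuaternion":
        w1, x1, y1, z1 = self.q
        w2, x2, y2, z2 = other.q
        return UnitQuaternion(
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        )

    def rotate(self, v) -> np.ndarray:
        """Rotate a 3-vector by this quaternion."""
        w, x, y, z = self.q
        u = np.array([x, y, z])
        v = np.asarray(v, dtype=float)
        return v + 2.0 * np.cross(u, np.cross(u, v) + w * v)

    def inner(self, other: "UnitQuaternion") -> float:
        return float(np.dot(self.q, other.q))

    def __repr__(self):
        return f"UnitQuaternion({', '.join(f'{c:.6g}' for c in self.q)})"


@dataclass
class Pose:
    rotation: UnitQuaternion
    translation: np.ndarray

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)


@dataclass
class PoseTrack:
    """Per-frame rigid poses of one named bone."""

    bone: str
    poses: list[Pose]

    def __len__(self) -> int:
        return len(self.poses)


@dataclass(frozen=True)
class TrialErrorSummary:
    """Across-frame mean and sample std of each error metric."""

    orientation_mean_deg: float
    orientation_std_deg: float
    position_mean_mm: float
    position_std_mm: float
    ncc_error_mean: float | None = None
    ncc_error_std: float | None = None

    def to_dict(self) -> dict:
        return {
            "orientation_mean_deg": self.orientation_mean_deg,
            "orientation_std_deg": self.orientation_std_deg,
            "position_mean_mm": self.position_mean_mm,
            "position_std_mm": self.position_std_mm,
            "ncc_error_mean": self.ncc_error_mean,
            "ncc_error_std": self.ncc_error_std,
        }


def orientation_error(p: UnitQuaternion, q: UnitQuaternion, degrees: bool = True) -> float:
    """Geodesic rotation distance 2*arccos(|<p,q>|), in [0, 180] degrees."""
    inner = min(1.0, abs(p.inner(q)))
    angle = 2.0 * math.acos(inner)
    return math.degrees(angle) if degrees else angle


def position_error(t_case, t_ref) -> float:
    """Euclidean distance (mm) between two translations."""
    return float(np.linalg.norm(np.asarray(t_case, float) - np.asarray(t_ref, float)))


def ncc_error(ncc_case: float, ncc_ref: float) -> float:
    """Case NCC normalized by the reference NCC: (case - ref) / ref."""
    if ncc_ref == 0:
        raise ValueError("reference NCC is zero; normalized error undefined")
    return (ncc_case - ncc_ref) / ncc_ref


def relative_pose(parent: Pose, child: Pose) -> Pose:
    """Child pose expressed in the parent's frame."""
    conj = parent.rotation.conjugate()
    return Pose(
        rotation=conj * child.rotation,
        translation=conj.rotate(child.translation - parent.translation),
    )


def compose(parent: Pose, rel: Pose) -> Pose:
    """Inverse of :func:`relative_pose`: parent frame ∘ relative pose."""
    return Pose(
        rotation=parent.rotation * rel.rotation,
        translation=parent.translation + parent.rotation.rotate(rel.translation),
    )


def _sample_std(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def summarize_trial(
    case_parent: PoseTrack,
    case_child: PoseTrack,
    ref_parent: PoseTrack,
    ref_child: PoseTrack,
    ncc_case=None,
    ncc_ref=None,
) -> TrialErrorSummary:
    """Per-frame relative poses -> per-frame errors -> mean/std per metric.

    The relative (child in parent frame) pose is formed per frame for both
    the case and the reference track; orientation and position errors
    compare the two relative poses.  Optional NCC series are normalized
    frame by frame.
    """
    lengths = {len(case_parent), len(case_child), len(ref_parent), len(ref_child)}
    if len(lengths) != 1:
        raise ValueError(f"track frame counts differ: {sorted(lengths)}")
    ori, pos = [], []
    for cp, cc, rp, rc in zip(
        case_parent.poses, case_child.poses, ref_parent.poses, ref_child.poses
    ):
        rel_case = relative_pose(cp, cc)
        rel_ref = relative_pose(rp, rc)
        ori.append(orientation_error(rel_case.rotation, rel_ref.rotation))
        pos.append(position_error(rel_case.translation, rel_ref.translation))
    ori = np.asarray(ori)
    pos = np.asarray(pos)
    ncc_mean = ncc_std = None
    if ncc_case is not None:
        ncc_case = np.asarray(ncc_case, dtype=float)
        ncc_ref = np.asarray(ncc_ref, dtype=float)
        if ncc_case.shape != ncc_ref.shape or len(ncc_case) != len(ori):
            raise ValueError("NCC series lengths must match the frame count")
        errs = np.array([ncc_error(c, r) for c, r in zip(ncc_case, ncc_ref)])
        ncc_mean, ncc_std = float(errs.mean()), _sample_std(errs)
    return TrialErrorSummary(
        orientation_mean_deg=float(ori.mean()),
        orientation_std_deg=_sample_std(ori),
        position_mean_mm=float(pos.mean()),
        position_std_mm=_sample_std(pos),
        ncc_error_mean=ncc_mean,
        ncc_error_std=ncc_std,
    )


# -- CSV I/O ---------------------------------------------------------------
# pose CSV header: frame,bone,q1,q2,q3,q4,tx,ty,tz  (q1 = scalar part)

def read_pose_tracks(path) -> dict[str, PoseTrack]:
    df = pd.read_csv(path)
    required = ["frame", "bone", "q1", "q2", "q3", "q4", "tx", "ty", "tz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pose CSV {path!r} is missing columns {missing}")
    tracks = {}
    for bone, grp in df.groupby("bone", sort=True):
        grp = grp.sort_values("frame")
        poses = [
            Pose(UnitQuaternion(r.q1, r.q2, r.q3, r.q4), (r.tx, r.ty, r.tz))
            for r in grp.itertuples()
        ]
        tracks[str(bone)] = PoseTrack(str(bone), poses)
    return tracks


def write_pose_tracks(tracks: dict[str, PoseTrack], path) -> None:
    rows = []
    for bone, track in tracks.items():
        for i, pose in enumerate(track.poses):
            q = pose.rotation.q
            rows.append(
                dict(frame=i, bone=bone, q1=q[0], q2=q[1], q3=q[2], q4=q[3],
                     tx=pose.translation[0], ty=pose.translation[1],
                     tz=pose.translation[2])
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ncc_series(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "ncc" not in df.columns:
        raise ValueError(f"NCC CSV {path!r} needs an 'ncc' column")
    if "frame" in df.columns:
        df = df.sort_values("frame")
    return df["ncc"].to_numpy(dtype=float)
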
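"""Joint angles from skeleton frames via the two-vector included angle.

Every angle in this package is the full 3-D *included* angle at a vertex
joint,

    theta = arccos( Vd . Vp / (|Vd| |Vp|) ),

where Vp runs from the vertex to a proximal reference joint and Vd from
the vertex to a distal one. 180 deg means the two segments are collinear
(straight arm); the frontal/sagittal-plane vocabulary of shoulder
abduction and elbow flexion describes the movement being performed, not
a projection applied to the data — no plane projection is performed by
default. A projection option exists for sensitivity analysis only.

Segment triples per movement (side-less names, resolved per side):

    shoulder abduction  : Hip, Shoulder, Elbow   (vertex Shoulder)
    shoulder adduction  : Hand, Shoulder, Hip    (vertex Shoulder)
    elbow flexion       : Shoulder, Elbow, Hand  (vertex Elbow)
    elbow extension     : Hand, Elbow, Shoulder  (vertex Elbow)

The adduction triple is hand-referenced, which is anatomically unusual;
it is kept verbatim as the system's operating definition and is fully
configurable. "Hand" means the Hand joints proper, not Wrist or HandTip.
Shoulder rotation, pronation/supination and wrist angles are out of
scope: the sensor's joint set cannot express them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, DomainError, EmptyStreamError, FrameExcluded
from .skeleton import SkeletonFrame, SkeletonStream, joint_for_side

MOVEMENTS = ("shoulder_abduction", "shoulder_adduction", "elbow_flexion", "elbow_extension")

#: Plane normals for the optional projection flag (camera space).
_PLANE_NORMALS = {"frontal": np.array([0.0, 0.0, 1.0]),
                  "sagittal": np.array([1.0, 0.0, 0.0])}

_MIN_NORM = 1e-9


@dataclass(frozen=True)
class SegmentDefinition:
    """The (vertex, proximal, distal) joint triple defining one movement's angle."""

    movement: str
    vertex: str
    proximal: str
    distal: str

    def __post_init__(self):
        if len({self.vertex, self.proximal, self.distal}) != 3:
            raise DomainError(f"segment joints must be distinct, got {self}")

    def resolve(self, side: str) -> tuple[str, str, str]:
        """Canonical sided joint names for (vertex, proximal, distal)."""
        return (joint_for_side(self.vertex, side),
                joint_for_side(self.proximal, side),
                joint_for_side(self.distal, side))


DEFAULT_SEGMENTS: dict[str, SegmentDefinition] = {
    "shoulder_abduction": SegmentDefinition("shoulder_abduction", "Shoulder", "Hip", "Elbow"),
    "shoulder_adduction": SegmentDefinition("shoulder_adduction", "Shoulder", "Hand", "Hip"),
    "elbow_flexion": SegmentDefinition("elbow_flexion", "Elbow", "Shoulder", "Hand"),
    "elbow_extension": SegmentDefinition("elbow_extension", "Elbow", "Hand", "Shoulder"),
}


@dataclass(frozen=True)
class AngleMeasurement:
    theta: float          # degrees, [0, 180]
    movement: str
    side: str
    frame_index: int


@dataclass
class AngleSeries:
    """Per-frame angle measurements for one movement/side, with exclusions."""

    movement: str
    side: str
    measurements: list[AngleMeasurement]
    excluded_frames: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        idx = [m.frame_index for m in self.measurements]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise DomainError("measurement frame indices must be strictly increasing")

    @property
    def thetas(self) -> np.ndarray:
        return np.array([m.theta for m in self.measurements], dtype=float)

    @property
    def frame_indices(self) -> list[int]:
        return [m.frame_index for m in self.measurements]

    def __len__(self) -> int:
        return len(self.measurements)


def angle_between(vd, vp) -> float:
    """Included angle between two 3-D vectors, in degrees in [0, 180].

    The cosine is clamped into [-1, 1] before arccos so that collinear
    vectors perturbed at machine precision stay in range. Invariant to
    positive rescaling of either argument; vectors shorter than 1e-9
    are rejected as degenerate.
    """
    vd = np.asarray(vd, dtype=float)
    vp = np.asarray(vp, dtype=float)
    nd, np_ = np.linalg.norm(vd), np.linalg.norm(vp)
    if nd < _MIN_NORM or np_ < _MIN_NORM:
        raise DegenerateGeometryError(
            f"vector norm below {_MIN_NORM} m (|Vd|={nd:.3g}, |Vp|={np_:.3g})")
    c = float(np.dot(vd, vp) / (nd * np_))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def joint_angle(
    frame: SkeletonFrame,
    movement: str,
    side: str,
    segments: SegmentDefinition | None = None,
    project_plane: str | None = None,
) -> AngleMeasurement:
    """Measure one movement's angle on one frame.

    Raises :class:`FrameExcluded` when a required joint is missing or
    not tracked — callers iterating over a stream catch this and log the
    frame — and :class:`DegenerateGeometryError` when the three joints
    are (numerically) coincident.

    ``project_plane`` ('frontal' or 'sagittal') projects both segment
    vectors onto the named anatomical plane before measuring; off by
    default.
    """
    if movement not in MOVEMENTS:
        raise DomainError(f"unknown movement {movement!r}; expected one of {MOVEMENTS}")
    seg = segments or DEFAULT_SEGMENTS[movement]
    names = seg.resolve(side)
    for name in names:
        if name not in frame.positions:
            raise FrameExcluded(f"joint {name} missing from frame {frame.frame_index}")
        if frame.state(name) == "not_tracked":
            raise FrameExcluded(f"joint {name} not_tracked in frame {frame.frame_index}")
    vertex, proximal, distal = (frame.positions[n] for n in names)
    vp = np.asarray(proximal, float) - np.asarray(vertex, float)
    vd = np.asarray(distal, float) - np.asarray(vertex, float)
    if project_plane is not None:
        try:
            n = _PLANE_NORMALS[project_plane]
        except KeyError:
            raise DomainError(f"unknown plane {project_plane!r}; "
                              f"expected one of {sorted(_PLANE_NORMALS)}") from None
        vp = vp - np.dot(vp, n) * n
        vd = vd - np.dot(vd, n) * n
    theta = angle_between(vd, vp)
    return AngleMeasurement(theta, movement, side, frame.frame_index)


def angle_series(
    stream: SkeletonStream,
    movement: str,
    side: str,
    segments: SegmentDefinition | None = None,
    project_plane: str | None = None,
) -> AngleSeries:
    """Measure every usable frame of a stream; bookkeep the unusable ones.

    Frames whose required joints are untracked/missing are excluded with
    a reason; degenerate-geometry frames likewise. An entirely unusable
    stream raises :class:`EmptyStreamError`.
    """
    if len(stream.frames) == 0:
        raise EmptyStreamError("cannot measure an empty stream")
    measurements: list[AngleMeasurement] = []
    excluded: list[tuple[int, str]] = []
    for frame in stream.frames:
        try:
            measurements.append(joint_angle(frame, movement, side, segments, project_plane))
        except FrameExcluded as exc:
            excluded.append((frame.frame_index, exc.reason))
        except DegenerateGeometryError as exc:
            excluded.append((frame.frame_index, f"degenerate geometry: {exc}"))
    if not measurements:
        raise EmptyStreamError(
            f"no usable frames for {movement}/{side}: "
            f"{len(excluded)} excluded (first: {excluded[0][1]})")
    return AngleSeries(movement, side, measurements, excluded)
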
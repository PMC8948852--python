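"""Data model and I/O for 25-joint skeleton streams.

The stream layout mirrors the markerless natural-user-interface (NUI)
skeleton of consumer depth sensors: 25 named joints per time-stamped
frame, 3-D positions in metres in camera space, sampled nominally at
30 Hz. Coordinate convention (documented here because sensor vendors do
not agree): x points to the camera's left — i.e. the participant's right
when they face the camera — y points up, z from the camera toward the
participant, origin at the sensor. The convention is isolated in
MIRROR_AXIS / mirror_frame so it can be flipped without touching the
geometry code.

Two on-disk dialects are supported interchangeably:

* CSV, one row per joint per frame, columns
  ``frame_index,timestamp_s,joint,x_m,y_m,z_m,tracking_state``;
* JSON-lines, one frame per line with an optional leading metadata line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyStreamError, SchemaError, StreamParseError

#: The 25 canonical joint names of the sensor's skeleton, in vendor order.
JOINT_NAMES: tuple[str, ...] = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)

JOINT_SET = frozenset(JOINT_NAMES)

TRACKING_STATES = ("tracked", "inferred", "not_tracked")

#: Axis whose sign flips under a left/right body-midline reflection.
MIRROR_AXIS = 0


def joint_for_side(base: str, side: str) -> str:
    """Resolve a side-less joint name ('Shoulder') to the canonical name.

    Lookup is total on the canonical vocabulary: midline joints pass
    through unchanged, sided joints get the side suffix appended.
    """
    if base in JOINT_SET:
        return base
    if side not in ("left", "right"):
        raise SchemaError(f"unknown side {side!r}; expected 'left' or 'right'")
    name = f"{base}{side.capitalize()}"
    if name not in JOINT_SET:
        raise SchemaError(f"unknown joint {base!r} (no canonical joint {name!r})")
    return name


@dataclass
class ValidationIssue:
    kind: str        # "missing_joint" | "non_finite" | "bad_state" | "bad_index"
    joint: str | None
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}({self.joint}): {self.detail}"


@dataclass
class SkeletonFrame:
    """One time-stamped sample of the full 25-joint skeleton."""

    frame_index: int
    timestamp: float
    positions: dict[str, np.ndarray]
    tracking: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.positions:
            self.positions[name] = np.asarray(self.positions[name], dtype=float)
        # default: every present joint fully tracked
        for name in self.positions:
            self.tracking.setdefault(name, "tracked")

    def state(self, joint: str) -> str:
        return self.tracking.get(joint, "not_tracked")


@dataclass
class SkeletonStream:
    """Ordered skeleton frames plus acquisition metadata."""

    frames: list[SkeletonFrame]
    rate: float = 30.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rate <= 0:
            raise SchemaError(f"rate must be > 0 Hz, got {self.rate}")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SchemaError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def validate_frame(frame: SkeletonFrame) -> list[ValidationIssue]:
    """Report every invariant violation in a frame; never raises.

    Returns an empty list iff the frame is well formed: all 25 joints
    present with finite coordinates and a recognised tracking state.
    """
    issues: list[ValidationIssue] = []
    try:
        if int(frame.frame_index) < 0:
            issues.append(ValidationIssue("bad_index", None,
                                          f"negative frame_index {frame.frame_index}"))
    except (TypeError, ValueError):
        issues.append(ValidationIssue("bad_index", None,
                                      f"non-integer frame_index {frame.frame_index!r}"))
    positions = getattr(frame, "positions", None) or {}
    for name in JOINT_NAMES:
        if name not in positions:
            issues.append(ValidationIssue("missing_joint", name, "joint absent from frame"))
            continue
        p = np.asarray(positions[name], dtype=float).ravel()
        if p.size != 3 or not np.all(np.isfinite(p)):
            issues.append(ValidationIssue("non_finite", name,
                                          f"coordinates {p.tolist()} not a finite 3-vector"))
        state = frame.state(name)
        if state not in TRACKING_STATES:
            issues.append(ValidationIssue("bad_state", name, f"unknown tracking state {state!r}"))
    for name in positions:
        if name not in JOINT_SET:
            issues.append(ValidationIssue("missing_joint", name, "not a canonical joint name"))
    return issues


def mirror_frame(frame: SkeletonFrame) -> SkeletonFrame:
    """Reflect a frame across the body midline, swapping Left/Right joints."""
    def swap(name: str) -> str:
        if name.endswith("Left"):
            return name[:-4] + "Right"
        if name.endswith("Right"):
            return name[:-5] + "Left"
        return name

    positions, tracking = {}, {}
    for name, p in frame.positions.items():
        q = np.array(p, dtype=float)
        q[MIRROR_AXIS] = -q[MIRROR_AXIS]
        positions[swap(name)] = q
        tracking[swap(name)] = frame.state(name)
    return SkeletonFrame(frame.frame_index, frame.timestamp, positions, tracking)


# --------------------------------------------------------------------------
# I/O

_CSV_COLUMNS = ["frame_index", "timestamp_s", "joint", "x_m", "y_m", "z_m", "tracking_state"]


def read_skeleton_stream(path: str | Path, rate: float = 30.0) -> SkeletonStream:
    """Read a skeleton stream from CSV or JSON-lines (chosen by extension).

    Frames are returned sorted by frame_index. Missing timestamps are
    derived as frame_index / rate. Malformed rows raise
    :class:`StreamParseError` naming the line; non-canonical joint names
    raise :class:`SchemaError`; an empty file raises
    :class:`EmptyStreamError`.
    """
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        return _read_jsonl(path, rate)
    return _read_csv(path, rate)


def _read_csv(path: Path, rate: float) -> SkeletonStream:
    try:
        table = pd.read_csv(path, dtype={"joint": str, "tracking_state": str})
    except pd.errors.EmptyDataError:
        raise EmptyStreamError(f"{path}: empty stream file") from None
    except (ValueError, pd.errors.ParserError) as exc:
        raise StreamParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in table.columns and c != "timestamp_s"]
    if missing:
        raise StreamParseError(f"{path}: missing required columns {missing}")
    if len(table) == 0:
        raise EmptyStreamError(f"{path}: stream has a header but no rows")

    bad = set(table["joint"]) - JOINT_SET
    if bad:
        raise SchemaError(f"{path}: unknown joint name(s) {sorted(bad)}")
    for col in ("x_m", "y_m", "z_m"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        if coerced.isna().any() and not table[col].isna().any():
            line = int(coerced.index[coerced.isna()][0]) + 2  # header + 1-based
            raise StreamParseError(f"{path}: non-numeric {col} at line {line}")
        table[col] = coerced

    frames: list[SkeletonFrame] = []
    for fi, group in table.groupby("frame_index", sort=True):
        positions = {r.joint: np.array([r.x_m, r.y_m, r.z_m]) for r in group.itertuples()}
        tracking = {r.joint: r.tracking_state for r in group.itertuples()}
        if "timestamp_s" in group.columns and group["timestamp_s"].notna().any():
            ts = float(group["timestamp_s"].iloc[0])
        else:
            ts = float(fi) / rate
        frames.append(SkeletonFrame(int(fi), ts, positions, tracking))
    return SkeletonStream(frames, rate=rate)


def _read_jsonl(path: Path, rate: float) -> SkeletonStream:
    frames: list[SkeletonFrame] = []
    metadata: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise StreamParseError(f"{path}: line {lineno}: {exc}") from exc
            if "metadata" in obj and "joints" not in obj:
                metadata = obj["metadata"]
                rate = float(obj.get("rate_hz", rate))
                continue
            try:
                joints = obj["joints"]
                fi = int(obj["frame_index"])
            except (KeyError, TypeError, ValueError) as exc:
                raise StreamParseError(f"{path}: line {lineno}: malformed frame ({exc})") from exc
            bad = set(joints) - JOINT_SET
            if bad:
                raise SchemaError(f"{path}: line {lineno}: unknown joint name(s) {sorted(bad)}")
            positions = {n: np.asarray(j["xyz"], dtype=float) for n, j in joints.items()}
            tracking = {n: j.get("state", "tracked") for n, j in joints.items()}
            ts = float(obj.get("timestamp_s", fi / rate))
            frames.append(SkeletonFrame(fi, ts, positions, tracking))
    if not frames:
        raise EmptyStreamError(f"{path}: empty stream file")
    frames.sort(key=lambda f: f.frame_index)
    return SkeletonStream(frames, rate=rate, metadata=metadata)


def write_skeleton_stream(stream: SkeletonStream, path: str | Path) -> None:
    """Write a stream to CSV or JSON-lines (chosen by extension).

    Positions round-trip through :func:`read_skeleton_stream` to within
    1e-9 m (coordinates are written with 17 significant digits).
    Refuses to write an empty stream.
    """
    if len(stream.frames) == 0:
        raise EmptyStreamError("refusing to write a 0-frame stream")
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        with open(path, "w", encoding="utf-8") as fh:
            if stream.metadata:
                fh.write(json.dumps({"metadata": stream.metadata, "rate_hz": stream.rate}) + "\n")
            for f in stream.frames:
                joints = {
                    n: {"xyz": [float(v) for v in f.positions[n]], "state": f.state(n)}
                    for n in f.positions
                }
                fh.write(json.dumps({"frame_index": f.frame_index,
                                     "timestamp_s": f.timestamp,
                                     "joints": joints}) + "\n")
        return
    rows = []
    for f in stream.frames:
        for n in JOINT_NAMES:
            if n not in f.positions:
                continue
            x, y, z = (float(v) for v in f.positions[n])
            rows.append((f.frame_index, f.timestamp, n, x, y, z, f.state(n)))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, float_format="%.17g")
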
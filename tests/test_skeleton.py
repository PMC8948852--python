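"""Skeleton data model and stream I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinarom import (
    JOINT_NAMES,
    SkeletonFrame,
    SkeletonStream,
    mirror_frame,
    read_skeleton_stream,
    validate_frame,
    write_skeleton_stream,
)
from kinarom.errors import EmptyStreamError, SchemaError, StreamParseError
from kinarom.skeleton import joint_for_side


def _frame(i, rng, state="tracked"):
    positions = {n: rng.normal(size=3) for n in JOINT_NAMES}
    tracking = {n: state for n in JOINT_NAMES}
    return SkeletonFrame(i, i / 30.0, positions, tracking)


def _stream(n=5, seed=0, state="tracked"):
    rng = np.random.default_rng(seed)
    return SkeletonStream([_frame(i, rng, state) for i in range(n)])


class TestJointVocabulary:
    def test_exactly_25_distinct_joints(self):
        assert len(JOINT_NAMES) == 25
        assert len(set(JOINT_NAMES)) == 25

    def test_side_resolution_is_total_on_vocabulary(self):
        assert joint_for_side("Shoulder", "left") == "ShoulderLeft"
        assert joint_for_side("Hip", "right") == "HipRight"
        assert joint_for_side("Head", "left") == "Head"  # midline passes through

    def test_non_canonical_name_rejected(self):
        with pytest.raises(SchemaError):
            joint_for_side("Forearm", "left")


@pytest.mark.parametrize("suffix", [".csv", ".jsonl"])
class TestRoundTrip:
    def test_positions_and_states_survive(self, tmp_path, suffix):
        stream = _stream(n=30)
        stream.frames[3].tracking["ElbowRight"] = "not_tracked"
        stream.frames[7].tracking["HipLeft"] = "inferred"
        path = tmp_path / f"s{suffix}"
        write_skeleton_stream(stream, path)
        back = read_skeleton_stream(path)
        assert len(back) == 30
        for f0, f1 in zip(stream.frames, back.frames):
            assert f1.frame_index == f0.frame_index
            assert set(f1.positions) == set(JOINT_NAMES)
            for n in JOINT_NAMES:
                assert np.allclose(f0.positions[n], f1.positions[n], atol=1e-9)
                assert f1.state(n) == f0.state(n)

    def test_zero_frame_stream_refused(self, tmp_path, suffix):
        with pytest.raises(EmptyStreamError):
            write_skeleton_stream(SkeletonStream([]), tmp_path / f"e{suffix}")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(1, 8), seed=st.integers(0, 1000))
def test_roundtrip_property_random_streams(tmp_path_factory, n, seed):
    """Read(write(stream)) preserves every coordinate to <= 1e-9 m."""
    stream = _stream(n=n, seed=seed)
    path = tmp_path_factory.mktemp("rt") / "s.csv"
    write_skeleton_stream(stream, path)
    back = read_skeleton_stream(path)
    worst = max(
        float(np.max(np.abs(f0.positions[j] - f1.positions[j])))
        for f0, f1 in zip(stream.frames, back.frames) for j in JOINT_NAMES)
    assert worst <= 1e-9


class TestReadErrors:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(EmptyStreamError):
            read_skeleton_stream(p)

    def test_header_only(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("frame_index,timestamp_s,joint,x_m,y_m,z_m,tracking_state\n")
        with pytest.raises(EmptyStreamError):
            read_skeleton_stream(p)

    def test_unknown_joint_name(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame_index,timestamp_s,joint,x_m,y_m,z_m,tracking_state\n"
                     "0,0.0,Elbow,0,0,0,tracked\n")
        with pytest.raises(SchemaError, match="Elbow"):
            read_skeleton_stream(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "mal.csv"
        p.write_text("frame_index,timestamp_s,joint,x_m,y_m,z_m,tracking_state\n"
                     "0,0.0,Head,0,0,0,tracked\n"
                     "0,0.0,Neck,zero,0,0,tracked\n")
        with pytest.raises(StreamParseError, match="line 3"):
            read_skeleton_stream(p)

    def test_frames_sorted_by_index(self, tmp_path):
        stream = _stream(n=4)
        path = tmp_path / "s.jsonl"
        write_skeleton_stream(stream, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(reversed(lines)) + "\n")
        back = read_skeleton_stream(path)
        assert [f.frame_index for f in back.frames] == [0, 1, 2, 3]

    def test_missing_timestamp_derived_from_rate(self, tmp_path):
        p = tmp_path / "nots.csv"
        rows = ["frame_index,timestamp_s,joint,x_m,y_m,z_m,tracking_state"]
        for i in range(2):
            rows += [f"{i},,{n},0.1,0.2,0.3,tracked" for n in JOINT_NAMES]
        p.write_text("\n".join(rows) + "\n")
        back = read_skeleton_stream(p, rate=30.0)
        assert back.frames[1].timestamp == pytest.approx(1 / 30.0)


class TestValidateFrame:
    def test_fully_tracked_frame_is_clean(self, tracked_frame):
        assert validate_frame(tracked_frame) == []

    def test_missing_joint_reported(self, tracked_frame):
        del tracked_frame.positions["HipLeft"]
        issues = validate_frame(tracked_frame)
        assert [i.kind for i in issues] == ["missing_joint"]
        assert issues[0].joint == "HipLeft"

    def test_nan_coordinate_reported(self, tracked_frame):
        tracked_frame.positions["Head"][1] = np.nan
        issues = validate_frame(tracked_frame)
        assert [i.kind for i in issues] == ["non_finite"]
        assert issues[0].joint == "Head"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.dictionaries(
        st.sampled_from(JOINT_NAMES + ("Bogus",)),
        st.lists(st.floats(allow_nan=True, allow_infinity=True), min_size=0, max_size=4),
        max_size=26))
    def test_validator_is_total_never_raises(self, positions):
        frame = SkeletonFrame(0, 0.0, {k: np.array(v, dtype=float) for k, v in positions.items()})
        assert isinstance(validate_frame(frame), list)


def test_mirror_swaps_sides_and_negates_axis(tracked_frame):
    m = mirror_frame(tracked_frame)
    assert np.allclose(m.positions["ShoulderLeft"][1:], tracked_frame.positions["ShoulderRight"][1:])
    assert m.positions["ShoulderLeft"][0] == -tracked_frame.positions["ShoulderRight"][0]
    assert m.state("ElbowLeft") == tracked_frame.state("ElbowRight")


def test_non_increasing_frame_index_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(SchemaError):
        SkeletonStream([_frame(1, rng), _frame(1, rng)])
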
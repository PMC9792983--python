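"""Strike-box segmentation, exclusion filters, direction and limb labels."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmat.errors import InvalidPassError
from gaitmat.footfall_detection import (
    DetectionParams,
    StrikeBox,
    _gap_tolerant_labels,
    assign_limbs,
    detect_direction,
    detect_strike_boxes,
    filter_noise,
    filter_partial_prints,
    validate_pass,
)
from gaitmat.walkway_io import MatGeometry, PressureRecording


def _make_box(box_id=0, first=0, last=10, cols=(0, 10), rows=(0, 5), area=50, limb="unassigned"):
    n = last - first + 1
    return StrikeBox(
        box_id=box_id,
        row_range=rows,
        col_range=cols,
        first_frame=first,
        last_frame=last,
        force_profile=np.ones(n),
        area=area,
        frame_rate=30.0,
        sensel_pitch=0.005,
        limb=limb,
        centroid_row=(rows[0] + rows[1]) / 2,
        centroid_col=(cols[0] + cols[1]) / 2,
    )


def _tiny_recording(frames):
    frames = np.asarray(frames, dtype=float)
    geometry = MatGeometry(
        n_rows=frames.shape[1], n_cols=frames.shape[2], sensel_pitch=0.005, frame_rate=30.0
    )
    return PressureRecording(
        geometry=geometry,
        frames=frames,
        timestamps=np.arange(frames.shape[0]) / 30.0,
    )


# ---------------------------------------------------------------------------
# brute-force flood-fill oracle (independent of the implementation)
# ---------------------------------------------------------------------------


def flood_fill_partition(volume, s_tol, t_tol):
    """Exhaustive O(n^2) connected components over active voxels: two
    voxels connect when frame indices differ by <= t_tol+1 and both
    spatial indices by <= s_tol+1."""
    coords = [tuple(c) for c in np.argwhere(volume)]
    parent = {c: c for c in coords}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(coords):
        for b in coords[i + 1 :]:
            if (
                abs(a[0] - b[0]) <= t_tol + 1
                and abs(a[1] - b[1]) <= s_tol + 1
                and abs(a[2] - b[2]) <= s_tol + 1
            ):
                parent[find(a)] = find(b)
    groups = {}
    for c in coords:
        groups.setdefault(find(c), set()).add(c)
    return {frozenset(g) for g in groups.values()}


def _implementation_partition(volume, s_tol, t_tol):
    coords = np.argwhere(volume)
    if len(coords) == 0:
        return set()
    labels = _gap_tolerant_labels(coords, volume.shape, s_tol, t_tol)
    groups = {}
    for c, lab in zip(coords, labels):
        groups.setdefault(lab, set()).add(tuple(c))
    return {frozenset(g) for g in groups.values()}


class TestSegmentationOracle:
    @given(
        seed=st.integers(0, 10_000),
        density=st.floats(0.05, 0.5),
        s_tol=st.integers(0, 2),
        t_tol=st.integers(0, 2),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_flood_fill_on_random_volumes(self, seed, density, s_tol, t_tol):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 9, size=3))
        volume = rng.random(shape) < density
        assert _implementation_partition(volume, s_tol, t_tol) == flood_fill_partition(
            volume, s_tol, t_tol
        )

    def test_single_print_matches_ground_truth_frames(self, clean_pass):
        recording, truth = clean_pass
        boxes = detect_strike_boxes(recording)
        assert len(boxes) == len(truth.footfalls)
        fr = recording.geometry.frame_rate
        for box in boxes:
            ff = min(
                truth.footfalls,
                key=lambda f: abs(f.t_on - box.first_time)
                + abs(min(f.heel_x, f.toe_x) - box.x_left),
            )
            assert abs(box.first_frame - ff.t_on * fr) <= 1.0 + 1e-9
            assert abs(box.last_frame - ff.t_off * fr) <= 1.0 + 1e-9
            assert box.x_left == pytest.approx(min(ff.heel_x, ff.toe_x), abs=0.005)

    def test_two_prints_overlapping_in_time(self):
        frames = np.zeros((6, 10, 30))
        frames[1:5, 2:4, 3:6] = 40.0
        frames[2:6, 7:9, 20:24] = 55.0
        boxes = detect_strike_boxes(_tiny_recording(frames))
        assert len(boxes) == 2

    def test_all_zero_recording_yields_empty_list(self):
        assert detect_strike_boxes(_tiny_recording(np.zeros((4, 5, 5)))) == []


class TestNoiseFilter:
    def test_two_frame_component_excluded(self):
        audit = []
        kept = filter_noise([_make_box(first=5, last=6)], audit=audit)
        assert kept == []
        assert audit[0]["rule"] == "noise"

    def test_three_frame_component_retained(self):
        boxes = [_make_box(first=5, last=7)]
        assert filter_noise(boxes) == boxes

    def test_empty_input(self):
        assert filter_noise([]) == []

    def test_idempotent(self):
        boxes = [_make_box(first=0, last=1), _make_box(box_id=1, first=0, last=20)]
        once = filter_noise(list(boxes))
        twice = filter_noise(list(once))
        assert once == twice


class TestPartialFilter:
    def _boxes(self):
        # three interior full prints + one small end print (cols near 0)
        return [
            _make_box(box_id=0, cols=(2, 10), area=30),
            _make_box(box_id=1, cols=(100, 114), area=90),
            _make_box(box_id=2, cols=(200, 214), area=88),
            _make_box(box_id=3, cols=(300, 314), area=92),
        ]

    def test_small_end_print_removed(self):
        geometry = MatGeometry.paper_mat()
        kept = filter_partial_prints(self._boxes(), geometry=geometry)
        assert [b.box_id for b in kept] == [1, 2, 3]

    def test_full_size_print_in_end_zone_retained(self):
        geometry = MatGeometry.paper_mat()
        boxes = self._boxes()
        boxes[0] = _make_box(box_id=0, cols=(2, 16), area=90)
        kept = filter_partial_prints(boxes, geometry=geometry)
        assert len(kept) == 4

    def test_small_mid_mat_print_retained(self):
        geometry = MatGeometry.paper_mat()
        boxes = self._boxes()
        boxes[0] = _make_box(box_id=0, cols=(150, 158), area=30)
        kept = filter_partial_prints(boxes, geometry=geometry)
        assert len(kept) == 4

    def test_fewer_than_three_boxes_unusable(self):
        with pytest.raises(InvalidPassError):
            filter_partial_prints([_make_box(), _make_box(box_id=1)])

    def test_idempotent(self):
        geometry = MatGeometry.paper_mat()
        once = filter_partial_prints(self._boxes(), geometry=geometry)
        twice = filter_partial_prints(list(once), geometry=geometry)
        assert once == twice


class TestDirection:
    def test_forward_pass(self, processed_clean):
        assert processed_clean["direction"] == 1

    def test_mirrored_pass_reverses(self, clean_pass):
        recording, _ = clean_pass
        mirrored = dataclasses.replace(recording, frames=recording.frames[:, :, ::-1].copy())
        boxes = detect_strike_boxes(mirrored)
        assert detect_direction(boxes) == -1

    def test_heel_is_trailing_edge(self, processed_clean):
        for box in processed_clean["boxes"]:
            assert box.heel_edge_x < box.toe_edge_x  # direction +1

    def test_single_box_invalid(self):
        with pytest.raises(InvalidPassError):
            detect_direction([_make_box()])


class TestLimbAssignment:
    def test_clean_pass_matches_ground_truth(self, clean_pass, processed_clean):
        _, truth = clean_pass
        boxes = processed_clean["boxes"]
        matched = 0
        for box in boxes:
            ff = min(
                truth.footfalls,
                key=lambda f: abs(f.t_on - box.first_time)
                + abs(min(f.heel_x, f.toe_x) - box.x_left),
            )
            matched += box.limb == ff.limb
        assert matched / len(boxes) >= 0.95

    def test_mirrored_pass_swaps_sides(self, clean_pass, processed_clean):
        recording, _ = clean_pass
        mirrored = dataclasses.replace(recording, frames=recording.frames[:, :, ::-1].copy())
        boxes = detect_strike_boxes(mirrored)
        direction = detect_direction(boxes)
        assign_limbs(boxes, direction, mirrored.geometry)
        swap = {"LF": "RF", "RF": "LF", "LH": "RH", "RH": "LH"}
        original = {
            (b.first_frame, round(b.centroid_row, 3)): b.limb
            for b in processed_clean["boxes"]
        }
        for box in boxes:
            key = (box.first_frame, round(box.centroid_row, 3))
            assert box.limb == swap[original[key]]

    def test_missing_track_left_unassigned(self, processed_clean):
        boxes = [
            dataclasses.replace(b) for b in processed_clean["boxes"] if b.limb != "LF"
        ]
        for b in boxes:
            b.limb = "unassigned"
        direction = detect_direction(boxes)
        assign_limbs(boxes, direction, MatGeometry.paper_mat())
        right = [b.limb for b in boxes if b.limb.startswith("R")]
        assert set(right) == {"RF", "RH"}


class TestPassValidity:
    def test_clean_pass_valid(self, processed_clean):
        verdict = validate_pass(processed_clean["boxes"])
        assert verdict.valid and verdict.reasons == []

    def test_inserted_dwell_flags_stopping(self, processed_clean):
        boxes = []
        for b in processed_clean["boxes"]:
            shifted = dataclasses.replace(b)
            if b.first_frame > 50:  # 2 s standstill inserted mid-pass
                shifted.first_frame += 60
                shifted.last_frame += 60
            boxes.append(shifted)
        verdict = validate_pass(boxes)
        assert not verdict.valid
        assert "stopping" in verdict.reasons

    def test_three_limb_pass_flags_limbs(self, processed_clean):
        boxes = [b for b in processed_clean["boxes"] if b.limb != "LF"]
        verdict = validate_pass(boxes)
        assert not verdict.valid
        assert "limbs" in verdict.reasons

    def test_backtracking_pass_flagged(self):
        boxes = []
        for i in range(8):
            col = 40 + 30 * i if i != 5 else 40  # one limb far behind
            boxes.append(
                _make_box(box_id=i, first=10 * i, last=10 * i + 12, cols=(col, col + 10),
                          limb=["LH", "LF", "RH", "RF"][i % 4])
            )
        verdict = validate_pass(boxes)
        assert "backtrack" in verdict.reasons


class TestArtifactRemovalEndToEnd:
    def test_blips_and_partials_removed_cleanly(self, clean_pass):
        from gaitmat.pipeline import process_recording
        from gaitmat.synthetic_gait import inject_noise_blips, truncate_end_prints

        recording, truth = clean_pass
        noisy, log = inject_noise_blips(recording, 4, seed=2)
        cropped, new_truth = truncate_end_prints(noisy, truth)
        result = process_recording(cropped)
        assert result["noise_excluded"] == len(log)
        assert result["partial_excluded"] == 2
        n_full = sum(not f.partial for f in new_truth.footfalls)
        assert len(result["boxes"]) == n_full
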
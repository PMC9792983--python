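"""Simulator: scheduling, rasterization, presets, artifact injection."""

import dataclasses

import numpy as np
import pytest

from gaitmat.errors import ConfigurationError, UsageError
from gaitmat.synthetic_gait import (
    GaitConfig,
    STATE_PRESETS,
    StatePreset,
    _check_preset_monotonicity,
    inject_noise_blips,
    simulate_cohort,
    simulate_pass,
    true_parameter_table,
    truncate_end_prints,
    truncate_footfall,
)
from gaitmat.walkway_io import frame_forces, write_recording


class TestConfig:
    def test_duty_factor_window_enforced(self):
        with pytest.raises(ConfigurationError):
            GaitConfig(stance_time_mean=0.2, swing_time_mean=0.3)  # duty 0.4

    def test_phase_offsets_must_be_distinct(self):
        with pytest.raises(ConfigurationError):
            GaitConfig(
                limb_phase_offsets=(("LH", 0.0), ("LF", 0.0), ("RH", 0.5), ("RF", 0.75))
            )

    def test_mat_too_short_for_pass(self):
        config = GaitConfig(n_strides=8)
        with pytest.raises(ConfigurationError, match="span"):
            simulate_pass(config)


class TestDeterminism:
    def test_identical_seed_identical_output(self, tmp_path):
        config = GaitConfig(seed=42)
        rec1, truth1 = simulate_pass(config)
        rec2, truth2 = simulate_pass(config)
        assert np.array_equal(rec1.frames, rec2.frames)
        assert [dataclasses.astuple(f) for f in truth1.footfalls] == [
            dataclasses.astuple(f) for f in truth2.footfalls
        ]
        p1, p2 = tmp_path / "a.pwm", tmp_path / "b.pwm"
        write_recording(rec1, p1)
        write_recording(rec2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        rec1, _ = simulate_pass(GaitConfig(seed=1))
        rec2, _ = simulate_pass(GaitConfig(seed=2))
        assert not np.array_equal(rec1.frames, rec2.frames)


class TestScheduling:
    def test_zero_sd_stride_times_exact(self, deterministic_pass):
        _, truth = deterministic_pass
        strides = truth.true_stride_table()
        assert len(strides) == 8  # 4 limbs x 2 strides
        assert strides["stride_time"].to_numpy() == pytest.approx(0.45, abs=1e-12)
        assert strides["stance_time"].to_numpy() == pytest.approx(0.30, abs=1e-12)
        assert strides["swing_time"].to_numpy() == pytest.approx(0.15, abs=1e-12)

    def test_footfall_count_and_heel_spacing(self, deterministic_pass):
        _, truth = deterministic_pass
        assert 8 <= len(truth.footfalls) <= 12
        config = truth.config
        for limb in ("LH", "LF", "RH", "RF"):
            ffs = truth.footfalls_for(limb)
            assert len(ffs) == config.n_strides + 1
            spacing = np.diff([f.heel_x for f in ffs])
            assert spacing == pytest.approx(config.stride_length_mean, abs=1e-12)

    def test_stride_time_is_stance_plus_swing_exactly(self):
        for seed in range(5):
            _, truth = simulate_pass(GaitConfig(seed=seed))
            strides = truth.true_stride_table()
            assert strides["stride_time"].to_numpy() == pytest.approx(
                (strides["stance_time"] + strides["swing_time"]).to_numpy(), abs=1e-12
            )
            assert strides["stride_length"].to_numpy() == pytest.approx(
                (strides["stance_length"] + strides["swing_length"]).to_numpy(),
                abs=1e-12,
            )

    def test_reverse_direction_pass(self):
        rec, truth = simulate_pass(GaitConfig(seed=3, direction=-1))
        # heel is the trailing edge: for right-to-left travel heel_x > toe_x
        for ff in truth.footfalls:
            assert ff.heel_x > ff.toe_x
        strides = truth.true_stride_table()
        assert (strides["stride_length"] > 0).all()


class TestRasterization:
    def test_weight_support_over_stride_cycle(self, clean_pass):
        recording, truth = clean_pass
        config = truth.config
        forces = frame_forces(recording)
        fr = recording.geometry.frame_rate
        mid = recording.n_frames // 2
        half = int(config.stride_time_mean * fr / 2)
        window = forces[mid - half : mid + half + 1]
        assert window.mean() == pytest.approx(config.subject_weight, rel=0.10)

    def test_pressures_quantized_for_writer(self, clean_pass):
        recording, _ = clean_pass
        nz = recording.frames[recording.frames > 0]
        printed = np.array([float(f"{v:.6g}") for v in nz[:500]])
        assert np.array_equal(printed, nz[:500])


class TestPresets:
    def test_shipped_presets_are_monotone(self):
        _check_preset_monotonicity(STATE_PRESETS)

    def test_severity_slows_gait(self):
        # implied speed and cadence fall monotonically along the ladder
        speeds, cadences = [], []
        for label in ("naive", "mild", "moderate", "severe"):
            cfg = STATE_PRESETS[label].apply(GaitConfig())
            speeds.append(cfg.stride_length_mean / cfg.stride_time_mean)
            cadences.append(1.0 / cfg.stride_time_mean)
        assert speeds == sorted(speeds, reverse=True)
        assert cadences == sorted(cadences, reverse=True)

    def test_stride_length_reduced_materially_only_at_severe(self):
        scales = [STATE_PRESETS[s].stride_length_scale for s in ("naive", "mild", "moderate", "severe")]
        assert scales[0] == scales[1] == 1.0
        assert scales[2] >= 0.95
        assert scales[3] <= 0.85

    def test_non_monotone_ladder_rejected(self):
        bad = dict(STATE_PRESETS)
        bad["severe"] = StatePreset("severe", 1.0, 1.0, 1.0, 0.5, 1.0)
        with pytest.raises(ConfigurationError):
            _check_preset_monotonicity(bad)


class TestNoiseBlips:
    def test_zero_blips_is_identity(self, clean_pass):
        recording, _ = clean_pass
        out, log = inject_noise_blips(recording, 0)
        assert out is recording
        assert log == []

    def test_blips_logged_with_short_spans(self, clean_pass):
        recording, _ = clean_pass
        out, log = inject_noise_blips(recording, 5, max_frames=2, seed=9)
        assert len(log) == 5
        assert all(entry["n_frames"] in (1, 2) for entry in log)
        # injected pressure present in the output at each logged location
        for entry in log:
            span = out.frames[
                entry["frame_start"] : entry["frame_start"] + entry["n_frames"],
                entry["row"],
                entry["col"],
            ]
            assert (span == entry["pressure"]).all()

    def test_blips_avoid_true_footfall_sensels(self, clean_pass):
        recording, _ = clean_pass
        footprint = recording.frames.max(axis=0) > 0
        _, log = inject_noise_blips(recording, 8, seed=4)
        for entry in log:
            assert not footprint[entry["row"], entry["col"]]


class TestTruncation:
    def test_end_print_areas_fall_below_fraction(self, clean_pass):
        recording, truth = clean_pass
        out, new_truth = truncate_end_prints(recording, truth, fraction=0.74)
        partials = [f for f in new_truth.footfalls if f.partial]
        assert len(partials) == 2
        # recompute per-print areas from the modified frames
        from gaitmat.footfall_detection import detect_strike_boxes

        boxes = detect_strike_boxes(out)
        areas = sorted(b.area for b in boxes)
        full = np.median(areas[2:])
        assert areas[0] < 0.74 * full
        assert areas[1] < 0.74 * full

    def test_interior_prints_untouched(self, clean_pass):
        recording, truth = clean_pass
        out, new_truth = truncate_end_prints(recording, truth)
        sgn = truth.direction
        ends = {
            min(truth.footfalls, key=lambda f: sgn * f.heel_x).limb,
            max(truth.footfalls, key=lambda f: sgn * f.toe_x).limb,
        }
        # frames restricted to a mid-mat column band are identical
        n_cols = recording.geometry.n_cols
        band = slice(n_cols // 3, 2 * n_cols // 3)
        assert np.array_equal(out.frames[:, :, band], recording.frames[:, :, band])
        assert ends  # the two truncated prints belong to real limbs

    def test_mid_pass_print_refused(self, clean_pass):
        recording, truth = clean_pass
        interior = sorted(truth.footfalls, key=lambda f: f.t_on)[4]
        with pytest.raises(UsageError):
            truncate_footfall(recording, truth, interior)

    def test_too_few_footfalls_rejected(self):
        recording, truth = simulate_pass(GaitConfig(seed=2, n_strides=1))
        with pytest.raises(ConfigurationError):
            truncate_end_prints(recording, truth)


class TestCohort:
    def test_counts_and_labels(self):
        recs, truths = simulate_cohort(
            ["naive", "severe"], 2, 3, seed=1, session_rel_sd=0.0
        )
        assert len(recs) == len(truths) == 12
        assert {r.state_label for r in recs} == {"naive", "severe"}
        assert len({r.pass_id for r in recs}) == 12
        sessions = {r.session_id for r in recs}
        assert len(sessions) == 4

    def test_empty_preset_set_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort([], 2, 3)

    def test_severe_slower_than_naive_at_scale(self):
        _, truths = simulate_cohort(
            ["naive", "severe"], 4, 50, seed=7, rasterize=False, session_rel_sd=0.02
        )
        speeds = {"naive": [], "severe": []}
        for t in truths:
            speeds[t.state_label].append(t.true_pass_summary()["gait_speed"])
        assert np.mean(speeds["severe"]) < np.mean(speeds["naive"])

    def test_zero_session_sd_shares_config_means(self):
        _, truths = simulate_cohort(
            ["naive"], 3, 2, seed=5, rasterize=False, session_rel_sd=0.0
        )
        means = {
            (t.session_id, t.config.stance_time_mean, t.config.stride_length_mean)
            for t in truths
        }
        assert len({m[1:] for m in means}) == 1

    def test_truth_table_schema(self):
        _, truths = simulate_cohort(["naive"], 2, 2, seed=3, rasterize=False)
        table = true_parameter_table(truths)
        assert set(table["parameter"].unique()) == {
            "stride_length",
            "stance_length",
            "swing_length",
            "stride_time",
            "stance_time",
            "swing_time",
            "stride_speed",
            "cadence",
            "gait_speed",
        }
        # 4 passes x (4 limbs x 2 strides x 7 params + 2 pass params)
        assert len(table) == 4 * (8 * 7 + 2)
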
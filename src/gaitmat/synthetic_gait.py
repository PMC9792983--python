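"""Synthetic quadrupedal walking passes with exact ground truth.

The generator emulates a ~10-12 kg quadruped (e.g. a macaque) crossing a
pressure walkway in a lateral-sequence walk: each hind-limb contact is
followed a quarter cycle later by the ipsilateral forelimb, at default
cycle offsets LH 0, LF 0.25, RH 0.5, RF 0.75.  Stride-to-stride
variation is drawn per body cycle (one stride time and length shared by
all four limbs, truncated-normal, plus per-limb stance draws and a small
length jitter — limbs ride one trunk); each stance is rasterized as an
elliptical print whose center of pressure migrates heel to toe under a
double-peaked force profile, normalized so that whole-mat force averaged
over a stride cycle approximates the subject's weight (quasi-static
support).

Severity presets (naive / mild / moderate / severe) scale the config
means and spreads so that cadence and speeds decrease, stance and swing
times increase, swing variability increases with severity, and stride
length drops materially only in the severe state.  Preset magnitudes are
free parameters of the simulator chosen to be physiologically plausible;
only their ordering across states is treated as meaningful.

Artifact injectors create the two defects the downstream filters must
remove: isolated pressure blips of at most two frames, and partial end
prints clipped by the mat boundary.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, UsageError
from .walkway_io import MatGeometry, PressureRecording, STANDARD_GRAVITY

LIMBS = ("LH", "LF", "RH", "RF")
FRONT_LIMBS = frozenset({"LF", "RF"})
LEFT_LIMBS = frozenset({"LH", "LF"})

#: Lateral-sequence walk: hind contact, then ipsilateral fore a quarter
#: cycle later.
DEFAULT_PHASE_OFFSETS = {"LH": 0.0, "LF": 0.25, "RH": 0.5, "RF": 0.75}

_MIN_EDGE_MARGIN = 0.02  # m kept free at each mat end when centering a pass


@dataclass(frozen=True)
class GaitConfig:
    """Generative parameters of one simulated pass.

    Times are seconds, lengths meters, pressures kPa, weight kgf.
    Defaults describe a healthy (naive) walk of an ~11 kgf subject:
    0.50 m strides, 0.55 s stance / 0.275 s swing (duty factor 2/3,
    cadence ~291 steps/min over all four limbs, speed ~0.6 m/s).
    """

    stride_length_mean: float = 0.50
    stride_length_sd: float = 0.02
    stance_time_mean: float = 0.55
    stance_time_sd: float = 0.015
    swing_time_mean: float = 0.275
    swing_time_sd: float = 0.015
    limb_phase_offsets: tuple = (
        ("LH", 0.0),
        ("LF", 0.25),
        ("RH", 0.5),
        ("RF", 0.75),
    )
    front_hind_spacing: float = 0.25
    lateral_offset: float = 0.06
    print_length: float = 0.07
    print_width: float = 0.04
    peak_pressure: float = 60.0
    subject_weight: float = 11.0
    direction: int = 1
    n_strides: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "stride_length_mean",
            "stance_time_mean",
            "swing_time_mean",
            "front_hind_spacing",
            "lateral_offset",
            "print_length",
            "print_width",
            "peak_pressure",
            "subject_weight",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("stride_length_sd", "stance_time_sd", "swing_time_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        offsets = dict(self.limb_phase_offsets)
        if set(offsets) != set(LIMBS):
            raise ConfigurationError("phase offsets must cover LH, LF, RH, RF")
        vals = list(offsets.values())
        if len(set(vals)) != 4 or any(not (0 <= v < 1) for v in vals):
            raise ConfigurationError("phase offsets must be distinct in [0, 1)")
        if self.direction not in (1, -1):
            raise ConfigurationError("direction must be +1 or -1")
        if self.n_strides < 1:
            raise ConfigurationError("n_strides must be >= 1")
        duty = self.duty_factor
        if not (0.5 < duty < 0.9):
            raise ConfigurationError(
                f"duty factor {duty:.3f} outside the walking range (0.5, 0.9)"
            )

    @property
    def phase_offsets(self) -> dict:
        return dict(self.limb_phase_offsets)

    @property
    def stride_time_mean(self) -> float:
        return self.stance_time_mean + self.swing_time_mean

    @property
    def duty_factor(self) -> float:
        """Fraction of the stride cycle spent in stance; > 0.5 for a walk."""
        return self.stance_time_mean / self.stride_time_mean


@dataclass(frozen=True)
class StatePreset:
    """Multiplicative adjustments turning a baseline config into a state.

    Construction asserts the directional ordering used across severity:
    increasing time scales (longer stance/swing, lower cadence and speed)
    and non-decreasing variability scales.
    """

    label: str
    stance_time_scale: float = 1.0
    swing_time_scale: float = 1.0
    stride_length_scale: float = 1.0
    time_sd_scale: float = 1.0
    length_sd_scale: float = 1.0

    def apply(self, config: GaitConfig) -> GaitConfig:
        return replace(
            config,
            stance_time_mean=config.stance_time_mean * self.stance_time_scale,
            swing_time_mean=config.swing_time_mean * self.swing_time_scale,
            stride_length_mean=config.stride_length_mean * self.stride_length_scale,
            stance_time_sd=config.stance_time_sd * self.time_sd_scale,
            swing_time_sd=config.swing_time_sd * self.time_sd_scale,
            stride_length_sd=config.stride_length_sd * self.length_sd_scale,
        )


#: Severity ladder. Times lengthen and variability grows monotonically;
#: stride length is materially reduced only in the severe state.
STATE_PRESETS: dict[str, StatePreset] = {
    "naive": StatePreset("naive"),
    "mild": StatePreset("mild", 1.15, 1.15, 1.00, 1.3, 1.3),
    "moderate": StatePreset("moderate", 1.35, 1.35, 0.95, 1.8, 1.8),
    "severe": StatePreset("severe", 1.75, 1.75, 0.80, 2.5, 2.5),
}

STATE_ORDER = ("naive", "mild", "moderate", "severe")


def _check_preset_monotonicity(presets: dict[str, StatePreset]) -> None:
    """Severity ordering of the shipped presets (asserted at import)."""
    ordered = [presets[s] for s in STATE_ORDER if s in presets]
    for a, b in zip(ordered, ordered[1:]):
        if b.stance_time_scale < a.stance_time_scale:
            raise ConfigurationError("stance time must not shorten with severity")
        if b.swing_time_scale < a.swing_time_scale:
            raise ConfigurationError("swing time must not shorten with severity")
        # implied cadence ~ 1/stride time and speed ~ length/time
        speed_a = a.stride_length_scale / max(a.stance_time_scale, a.swing_time_scale)
        speed_b = b.stride_length_scale / max(b.stance_time_scale, b.swing_time_scale)
        if speed_b > speed_a:
            raise ConfigurationError("gait speed must not rise with severity")
        if b.time_sd_scale < a.time_sd_scale:
            raise ConfigurationError("swing variability must not fall with severity")


_check_preset_monotonicity(STATE_PRESETS)


@dataclass
class Footfall:
    """One ground-truth limb contact."""

    limb: str
    index: int
    t_on: float
    t_off: float
    heel_x: float
    toe_x: float
    y_center: float
    partial: bool = False

    @property
    def stance_time(self) -> float:
        return self.t_off - self.t_on


@dataclass
class GroundTruth:
    """Generative truth for a pass: every contact plus pass metadata."""

    footfalls: list
    config: GaitConfig
    geometry: MatGeometry
    subject_id: str = ""
    state_label: str = ""
    session_id: str = ""
    pass_id: str = ""

    @property
    def direction(self) -> int:
        return self.config.direction

    def footfalls_for(self, limb: str, include_partial: bool = True) -> list:
        out = [f for f in self.footfalls if f.limb == limb]
        if not include_partial:
            out = [f for f in out if not f.partial]
        return sorted(out, key=lambda f: f.t_on)

    def _signed(self, x: float) -> float:
        """Coordinate along the travel direction (m, increasing forward)."""
        return self.direction * x

    def true_stride_table(self, include_partial: bool = False) -> pd.DataFrame:
        """Per-stride truth following the strike-box parameter semantics.

        For consecutive contacts k, k+1 of one limb: d1/d2 are the heel
        and toe edges of stance k, d3 the heel edge of stance k+1; t1/t2
        the first/last contact times of stance k, t3 the first contact
        of stance k+1.
        """
        rows = []
        for limb in LIMBS:
            ffs = self.footfalls_for(limb)
            for a, b in zip(ffs, ffs[1:]):
                if not include_partial and (a.partial or b.partial):
                    continue
                d1, d2 = self._signed(a.heel_x), self._signed(a.toe_x)
                d3 = self._signed(b.heel_x)
                t1, t2, t3 = a.t_on, a.t_off, b.t_on
                rows.append(
                    {
                        "limb": limb,
                        "stride_length": d3 - d1,
                        "stance_length": d2 - d1,
                        "swing_length": d3 - d2,
                        "stride_time": t3 - t1,
                        "stance_time": t2 - t1,
                        "swing_time": t3 - t2,
                        "stride_speed": (d3 - d1) / (t3 - t1),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "limb",
                "stride_length",
                "stance_length",
                "swing_length",
                "stride_time",
                "stance_time",
                "swing_time",
                "stride_speed",
            ],
        )

    def true_pass_summary(self, include_partial: bool = False) -> dict:
        """True cadence (steps/min) and gait speed (m/s) of the pass."""
        ffs = [f for f in self.footfalls if include_partial or not f.partial]
        if len(ffs) < 2:
            raise ConfigurationError("need >= 2 footfalls for a pass summary")
        first = min(ffs, key=lambda f: f.t_on)
        last = max(ffs, key=lambda f: f.t_off)
        t_n = last.t_off - first.t_on
        d_n = self._signed(last.toe_x) - self._signed(first.heel_x)
        return {
            "n_stances": len(ffs),
            "dN": d_n,
            "tN": t_n,
            "cadence": len(ffs) / t_n * 60.0,
            "gait_speed": d_n / t_n,
        }


# ---------------------------------------------------------------------------
# scheduling
# ---------------------------------------------------------------------------


def _draw_positive(
    rng: np.random.Generator, mean: float, sd: float, size: int, lower: float = 0.0
) -> np.ndarray:
    """Normal draws truncated below ``lower`` (rejection sampling)."""
    if sd == 0:
        if mean <= lower:
            raise ConfigurationError(f"mean {mean} at or below truncation bound {lower}")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ConfigurationError("could not draw positive gait parameters; sd too large")


#: Per-limb jitter around the shared body cycle, as a fraction of the
#: configured stride-length sd (limbs ride one trunk, so most stride-to-
#: stride variation is common to all four limbs).
_LIMB_JITTER_FRACTION = 0.2


def _plan_footfalls(config: GaitConfig, geometry: MatGeometry, rng: np.random.Generator) -> list:
    """Schedule every limb contact in time and along the travel axis.

    Stride-to-stride variation is drawn at the body level: one stride
    time and one stride length per cycle, shared by all four limbs (plus
    a small per-limb jitter), with per-limb stance-time draws; swing time
    is the remainder of the cycle.  This keeps the limbs phase-locked the
    way a real trunk does, so prints never drift into one another, while
    every per-stride quantity still varies with the configured sds.
    """
    phases = config.phase_offsets
    t0 = config.stride_time_mean
    l0 = config.stride_length_mean
    n_contacts = config.n_strides + 1
    n_strides = config.n_strides

    stride_time_sd = math.hypot(config.stance_time_sd, config.swing_time_sd)
    cycle_times = _draw_positive(rng, t0, stride_time_sd, n_strides)
    # a walking quadruped never steps onto its own ipsilateral forelimb
    # print: the body advance per cycle stays above spacing + print length
    min_cycle_length = config.front_hind_spacing + config.print_length + 0.02
    if l0 <= min_cycle_length:
        raise ConfigurationError(
            f"stride_length_mean {l0} must exceed front_hind_spacing + "
            f"print_length + 0.02 = {min_cycle_length}"
        )
    cycle_lengths = _draw_positive(
        rng, l0, config.stride_length_sd, n_strides, lower=min_cycle_length
    )

    # spatial anchor: the front print of each cycle sits front_hind_spacing
    # ahead of the ipsilateral hind print (so the interlimb length equals
    # the spacing by construction); temporal phasing follows the limb's
    # own cycle offset
    hind_of = {"LH": "LH", "RH": "RH", "LF": "LH", "RF": "RH"}
    raw: dict[str, dict[str, np.ndarray]] = {}
    for limb in LIMBS:
        stance = _draw_positive(rng, config.stance_time_mean, config.stance_time_sd, n_contacts)
        jitter = (
            rng.normal(0.0, _LIMB_JITTER_FRACTION * config.stride_length_sd, n_strides)
            if config.stride_length_sd > 0
            else np.zeros(n_strides)
        )
        length = np.maximum(cycle_lengths + jitter, 1e-3)
        t_on = np.empty(n_contacts)
        s_heel = np.empty(n_contacts)
        t_on[0] = phases[limb] * t0
        s_heel[0] = phases[hind_of[limb]] * l0 + (
            config.front_hind_spacing if limb in FRONT_LIMBS else 0.0
        )
        for k in range(n_strides):
            swing = cycle_times[k] - stance[k]
            if swing <= 0:
                raise ConfigurationError(
                    "drawn stance time exceeds the cycle time; reduce the sds"
                )
            t_on[k + 1] = t_on[k] + stance[k] + swing
            s_heel[k + 1] = s_heel[k] + length[k]
        raw[limb] = {"t_on": t_on, "t_off": t_on + stance, "s_heel": s_heel}

    s_min = min(r["s_heel"][0] for r in raw.values())
    s_max = max(r["s_heel"][-1] for r in raw.values()) + config.print_length
    span = s_max - s_min
    usable = geometry.active_length - 2 * _MIN_EDGE_MARGIN
    if span > usable:
        raise ConfigurationError(
            f"pass span {span:.3f} m exceeds usable mat length {usable:.3f} m; "
            "shorten strides or the pass"
        )
    shift = (geometry.active_length - span) / 2 - s_min
    t_start = 0.2 - min(r["t_on"][0] for r in raw.values())

    mid_y = geometry.active_width / 2
    footfalls = []
    for limb in LIMBS:
        side = 1.0 if limb in LEFT_LIMBS else -1.0
        y_c = mid_y + side * config.lateral_offset * config.direction
        for k in range(n_contacts):
            s_heel = raw[limb]["s_heel"][k] + shift
            s_toe = s_heel + config.print_length
            if config.direction == 1:
                heel_x, toe_x = s_heel, s_toe
            else:
                heel_x = geometry.active_length - s_heel
                toe_x = geometry.active_length - s_toe
            footfalls.append(
                Footfall(
                    limb=limb,
                    index=k,
                    t_on=raw[limb]["t_on"][k] + t_start,
                    t_off=raw[limb]["t_off"][k] + t_start,
                    heel_x=heel_x,
                    toe_x=toe_x,
                    y_center=y_c,
                )
            )
    footfalls.sort(key=lambda f: f.t_on)
    return footfalls


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

# Double-peaked stance force profile (heel strike / toe-off peaks with a
# mid-stance valley) riding on a floor so contact pressure never vanishes
# inside the stance interval.
_PROFILE_FLOOR = 0.25


def _force_profile(u: np.ndarray) -> np.ndarray:
    return _PROFILE_FLOOR + 0.75 * np.sin(np.pi * u) * (1 + 0.4 * np.cos(2 * np.pi * u))


_PROFILE_MEAN = float(np.mean(_force_profile(np.linspace(0, 1, 20001))))


def _round_sig(a: np.ndarray, sig: int = 6) -> np.ndarray:
    """Round to ``sig`` significant decimal digits (writer-exact values)."""
    a = np.array(a, dtype=float)
    nz = a != 0
    mag = np.floor(np.log10(np.abs(a[nz])))
    factor = 10.0 ** (sig - 1 - mag)
    a[nz] = np.round(a[nz] * factor) / factor
    return a


def _rasterize(footfalls: list, config: GaitConfig, geometry: MatGeometry) -> np.ndarray:
    fr = geometry.frame_rate
    pitch = geometry.sensel_pitch
    n_frames = int(math.floor(max(f.t_off for f in footfalls) * fr)) + 3
    frames = np.zeros((n_frames, geometry.n_rows, geometry.n_cols))

    # mean stance force per limb so that the stride-cycle average over all
    # limbs supports the subject's weight
    mean_force = config.subject_weight / (4 * config.duty_factor)

    for ff in footfalls:
        x_lo, x_hi = sorted((ff.heel_x, ff.toe_x))
        a = (x_hi - x_lo) / 2
        b = config.print_width / 2
        xc, yc = (x_lo + x_hi) / 2, ff.y_center
        c0 = max(int(np.floor(x_lo / pitch - 0.5)) + 1, 0)
        c1 = min(int(np.ceil(x_hi / pitch - 0.5)), geometry.n_cols - 1)
        r0 = max(int(np.floor((yc - b) / pitch - 0.5)) + 1, 0)
        r1 = min(int(np.ceil((yc + b) / pitch - 0.5)), geometry.n_rows - 1)
        if c1 < c0 or r1 < r0:
            continue
        xs = (np.arange(c0, c1 + 1) + 0.5) * pitch
        ys = (np.arange(r0, r1 + 1) + 0.5) * pitch
        xx, yy = np.meshgrid(xs, ys)
        inside = ((xx - xc) / a) ** 2 + ((yy - yc) / b) ** 2 <= 1.0
        if not inside.any():
            continue
        f0 = max(int(np.floor(ff.t_on * fr + 1e-9)), 0)
        f1 = min(int(np.ceil(ff.t_off * fr - 1e-9)) - 1, n_frames - 1)
        gy = np.exp(-0.5 * ((yy - yc) / (0.6 * b)) ** 2)
        for f in range(f0, f1 + 1):
            t_mid = (f + 0.5) / fr
            u = np.clip((t_mid - ff.t_on) / (ff.t_off - ff.t_on), 0.0, 1.0)
            force = mean_force * _force_profile(np.array(u)) / _PROFILE_MEAN
            cop_x = ff.heel_x + (0.2 + 0.6 * u) * (ff.toe_x - ff.heel_x)
            gx = np.exp(-0.5 * ((xx - cop_x) / (0.35 * a)) ** 2)
            w = (0.15 + gx * gy) * inside
            pressure = force * STANDARD_GRAVITY / (1000.0 * pitch**2) * w / w.sum()
            frames[f, r0 : r1 + 1, c0 : c1 + 1] += pressure
    return frames


def simulate_pass(
    config: GaitConfig, geometry: MatGeometry | None = None
) -> tuple[PressureRecording, GroundTruth]:
    """Simulate one continuous walking pass.

    Returns the rasterized recording (pressures quantized to the 6
    significant digits the ``.pwm`` writer emits, so write/read
    round-trips are bit-exact) and the exact generative ground truth.
    Identical ``(config, geometry)`` gives bit-identical output.
    """
    geometry = geometry or MatGeometry.paper_mat()
    rng = np.random.default_rng(config.seed)
    footfalls = _plan_footfalls(config, geometry, rng)
    frames = _round_sig(_rasterize(footfalls, config, geometry))
    n = frames.shape[0]
    recording = PressureRecording(
        geometry=geometry,
        frames=frames,
        timestamps=np.arange(n) / geometry.frame_rate,
        calibration_weight=config.subject_weight,
    )
    truth = GroundTruth(footfalls=footfalls, config=config, geometry=geometry)
    return recording, truth


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------


def inject_noise_blips(
    recording: PressureRecording,
    n_blips: int,
    max_frames: int = 2,
    seed: int = 0,
) -> tuple[PressureRecording, list]:
    """Add isolated momentary pressure events away from any real print.

    Each blip occupies a single sensel for 1..``max_frames`` consecutive
    frames at a location that is never active in the original recording
    (with a safety margin, so blips can never merge with a print or with
    each other under gap-tolerant segmentation).  Returns the modified
    recording and a log of the injected events.
    """
    if n_blips < 0:
        raise UsageError("n_blips must be >= 0")
    if n_blips == 0:
        return recording, []
    rng = np.random.default_rng(seed)
    footprint = recording.frames.max(axis=0) > 0
    occupied = ndimage.binary_dilation(footprint, iterations=4)
    frames = recording.frames.copy()
    log = []
    for _ in range(n_blips):
        free = np.argwhere(~occupied)
        if len(free) == 0:
            raise UsageError("no free sensels left for blip injection")
        r, c = free[rng.integers(len(free))]
        span = int(rng.integers(1, max_frames + 1))
        f = int(rng.integers(0, recording.n_frames - span + 1))
        value = float(_round_sig(np.array(rng.uniform(5.0, 30.0))))
        frames[f : f + span, r, c] = value
        mark = np.zeros_like(occupied)
        mark[r, c] = True
        occupied |= ndimage.binary_dilation(mark, iterations=4)
        log.append(
            {"row": int(r), "col": int(c), "frame_start": f, "n_frames": span, "pressure": value}
        )
    out = replace(recording, frames=frames)
    return out, log


def _shift_block_toward_end(
    frames: np.ndarray,
    rows: slice,
    cols: slice,
    frame_range: slice,
    toward_low_cols: bool,
    fraction: float,
) -> int:
    """Translate a print block off the mat edge until its remaining
    ever-active area drops below ``fraction`` of the original; returns the
    shift in sensels."""
    block = frames[frame_range, rows, cols].copy()
    active = block.max(axis=0) > 0
    full_area = int(active.sum())
    width = block.shape[2]
    target = fraction * 0.85 * full_area
    lo = cols.start
    n_cols_total = frames.shape[2]
    shift = None
    for d in range(1, n_cols_total + width):
        if toward_low_cols:
            cut = max(0, d - lo)  # columns pushed below col 0 are lost
            remaining = active[:, cut:].sum() if cut < width else 0
        else:
            overflow = max(0, (lo + width + d) - n_cols_total)
            remaining = active[:, : width - overflow].sum() if overflow < width else 0
        if remaining <= target:
            shift = d
            break
    if shift is None:
        raise ConfigurationError("could not truncate print below target area")

    frames[frame_range, rows, cols] = 0.0
    if toward_low_cols:
        cut = max(0, shift - lo)
        if cut < width:
            dest = slice(lo - shift + cut, lo - shift + width)
            frames[frame_range, rows, dest] += block[:, :, cut:]
        return -shift
    overflow = max(0, (lo + width + shift) - n_cols_total)
    if overflow < width:
        dest = slice(lo + shift, lo + shift + width - overflow)
        frames[frame_range, rows, dest] += block[:, :, : width - overflow]
    return shift


def _end_footfalls(truth: GroundTruth) -> tuple[Footfall, Footfall]:
    sgn = truth.direction
    first = min(truth.footfalls, key=lambda f: sgn * f.heel_x)
    last = max(truth.footfalls, key=lambda f: sgn * f.toe_x)
    return first, last


def truncate_end_prints(
    recording: PressureRecording,
    truth: GroundTruth,
    fraction: float = 0.75,
) -> tuple[PressureRecording, GroundTruth]:
    """Clip the first and last spatial prints at the mat ends.

    Emulates a subject stepping partly off the walkway at the end
    enclosures: the spatially first and last prints are translated toward
    their nearest mat end and clipped by the boundary until their on-mat
    area falls below ``fraction`` of the full print area.  The returned
    ground truth marks both footfalls as partial (their true edges follow
    the shift).  Only the two end prints may be truncated; interior
    prints are untouched.
    """
    for limb in LIMBS:
        if len(truth.footfalls_for(limb)) < 3:
            raise ConfigurationError(
                "truncation needs >= 3 footfalls per limb so full end strides remain"
            )
    frames = recording.frames.copy()
    new_truth = copy.deepcopy(truth)
    first, last = _end_footfalls(new_truth)
    for ff in (first, last):
        _truncate_one(frames, recording.geometry, new_truth.config, ff, fraction)
    return replace(recording, frames=frames), new_truth


def _truncate_one(
    frames: np.ndarray,
    geometry: MatGeometry,
    config: GaitConfig,
    ff: Footfall,
    fraction: float,
) -> None:
    pitch = geometry.sensel_pitch
    fr = geometry.frame_rate
    n_frames = frames.shape[0]
    toward_low = min(ff.heel_x, ff.toe_x) < geometry.active_length / 2
    x_lo, x_hi = sorted((ff.heel_x, ff.toe_x))
    c0 = max(int(np.floor(x_lo / pitch - 0.5)), 0)
    c1 = min(int(np.ceil(x_hi / pitch + 0.5)), geometry.n_cols - 1)
    b = config.print_width / 2
    r0 = max(int(np.floor((ff.y_center - b) / pitch)) - 1, 0)
    r1 = min(int(np.ceil((ff.y_center + b) / pitch)) + 1, geometry.n_rows - 1)
    f0 = max(int(np.floor(ff.t_on * fr + 1e-9)), 0)
    f1 = min(int(np.ceil(ff.t_off * fr - 1e-9)) - 1, n_frames - 1)
    shift = _shift_block_toward_end(
        frames,
        slice(r0, r1 + 1),
        slice(c0, c1 + 1),
        slice(f0, f1 + 1),
        toward_low_cols=toward_low,
        fraction=fraction,
    )
    ff.heel_x += shift * pitch
    ff.toe_x += shift * pitch
    ff.partial = True


def truncate_footfall(
    recording: PressureRecording,
    truth: GroundTruth,
    footfall: Footfall,
    fraction: float = 0.75,
) -> tuple[PressureRecording, GroundTruth]:
    """Truncate a single end print; mid-pass prints are refused."""
    first, last = _end_footfalls(truth)
    if footfall not in (first, last):
        raise UsageError("only the spatially first or last print may be truncated")
    frames = recording.frames.copy()
    new_truth = copy.deepcopy(truth)
    target = next(
        f
        for f in new_truth.footfalls
        if (f.limb, f.index) == (footfall.limb, footfall.index)
    )
    _truncate_one(frames, recording.geometry, new_truth.config, target, fraction)
    return replace(recording, frames=frames), new_truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    presets,
    n_sessions_per_state: int,
    n_passes_per_session: int,
    base_config: GaitConfig | None = None,
    geometry: MatGeometry | None = None,
    seed: int = 0,
    session_rel_sd: float = 0.02,
    subject_id: str = "S1",
    rasterize: bool = True,
) -> tuple[list, list]:
    """Hierarchical cohort: states -> sessions -> passes.

    Session-level multiplicative offsets (relative sd ``session_rel_sd``,
    mean 1) perturb the stance/swing/stride means of all passes in a
    session; pass-level variation comes from the per-stride draws.  Every
    recording and ground truth carries subject/state/session/pass labels.
    With ``rasterize=False`` only ground truths are produced (fast path
    for statistical studies that work at the parameter level).
    """
    if not presets:
        raise ConfigurationError("preset set must not be empty")
    presets = [STATE_PRESETS[p] if isinstance(p, str) else p for p in presets]
    base_config = base_config or GaitConfig()
    geometry = geometry or MatGeometry.paper_mat()
    root = np.random.SeedSequence(seed)
    recordings: list[PressureRecording] = []
    truths: list[GroundTruth] = []
    for preset in presets:
        state_cfg = preset.apply(base_config)
        state_ss = root.spawn(1)[0]
        for s in range(n_sessions_per_state):
            sess_ss = state_ss.spawn(1)[0]
            sess_rng = np.random.default_rng(sess_ss)
            if session_rel_sd > 0:
                factors = 1.0 + session_rel_sd * sess_rng.standard_normal(3)
                factors = np.clip(factors, 0.5, 1.5)
            else:
                factors = np.ones(3)
            sess_cfg = replace(
                state_cfg,
                stance_time_mean=state_cfg.stance_time_mean * factors[0],
                swing_time_mean=state_cfg.swing_time_mean * factors[1],
                stride_length_mean=state_cfg.stride_length_mean * factors[2],
            )
            session_id = f"{preset.label}-s{s}"
            for p in range(n_passes_per_session):
                pass_cfg = replace(sess_cfg, seed=_child_seed(sess_ss.spawn(1)[0]))
                pass_id = f"{session_id}-p{p}"
                if rasterize:
                    rec, truth = simulate_pass(pass_cfg, geometry)
                    rec.subject_id = subject_id
                    rec.state_label = preset.label
                    rec.session_id = session_id
                    rec.pass_id = pass_id
                    recordings.append(rec)
                else:
                    rng = np.random.default_rng(pass_cfg.seed)
                    footfalls = _plan_footfalls(pass_cfg, geometry, rng)
                    truth = GroundTruth(footfalls=footfalls, config=pass_cfg, geometry=geometry)
                truth.subject_id = subject_id
                truth.state_label = preset.label
                truth.session_id = session_id
                truth.pass_id = pass_id
                truths.append(truth)
    return recordings, truths


def true_parameter_table(truths: list) -> pd.DataFrame:
    """Tidy long-format table of ground-truth gait parameters.

    Same schema as the pipeline's measured parameter table (subject,
    state, session, pass, limb, limb_group, parameter, value, units) so
    statistical routines can run on truth directly.
    """
    rows = []
    for truth in truths:
        strides = truth.true_stride_table()
        for limb, sub in strides.groupby("limb", sort=False):
            group = "front" if limb in FRONT_LIMBS else "hind"
            for i, (_, rec) in enumerate(sub.iterrows()):
                for param, unit in (
                    ("stride_length", "m"),
                    ("stance_length", "m"),
                    ("swing_length", "m"),
                    ("stride_time", "s"),
                    ("stance_time", "s"),
                    ("swing_time", "s"),
                    ("stride_speed", "m/s"),
                ):
                    rows.append(
                        (
                            truth.subject_id,
                            truth.state_label,
                            truth.session_id,
                            truth.pass_id,
                            limb,
                            group,
                            i,
                            param,
                            rec[param],
                            unit,
                        )
                    )
        summary = truth.true_pass_summary()
        for param, unit in (("cadence", "steps/min"), ("gait_speed", "m/s")):
            rows.append(
                (
                    truth.subject_id,
                    truth.state_label,
                    truth.session_id,
                    truth.pass_id,
                    "all",
                    "all",
                    0,
                    param,
                    summary[param],
                    unit,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "state",
            "session",
            "pass",
            "limb",
            "limb_group",
            "stride_index",
            "parameter",
            "value",
            "units",
        ],
    )
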
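"""Pressure-walkway recordings: container, on-disk dialect, force conversion.

A recording is a time-ordered stack of calibrated pressure grids (kPa)
sampled from a resistive sensel mat at a fixed frame rate.  The on-disk
format (".pwm") is a plain-text dialect: a ``key = value`` header block
followed by one ``FRAME`` block per sample, so that recordings are
inspectable, diffable and reproducible without vendor software.

Forces are expressed in kilogram-force (kgf): the aggregate of
``pressure x sensel_area`` over a region, divided by standard gravity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError, FormatError, FrameDimensionError

#: Standard gravity (m/s^2) used for the kPa -> kgf conversion.
STANDARD_GRAVITY = 9.80665

_TIMESTAMP_TOL = 1e-9


@dataclass(frozen=True)
class MatGeometry:
    """Geometry and sampling of a pressure-walkway mat.

    The sensel grid is authoritative: the active sensing area is
    ``n_cols * sensel_pitch`` long (walking axis) by
    ``n_rows * sensel_pitch`` wide.  The nominal footprint printed on a
    vendor datasheet may differ slightly and is metadata only.

    Parameters
    ----------
    n_rows
        Sensel count across the mat width.
    n_cols
        Sensel count along the walking axis.
    sensel_pitch
        Distance in meters between adjacent sensel centers (both axes).
    frame_rate
        Sampling rate in frames per second.
    """

    n_rows: int
    n_cols: int
    sensel_pitch: float
    frame_rate: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.sensel_pitch <= 0:
            raise ValueError("sensel_pitch must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def active_length(self) -> float:
        """Length (m) of the sensing area along the walking axis."""
        return self.n_cols * self.sensel_pitch

    @property
    def active_width(self) -> float:
        """Width (m) of the sensing area across the walking axis."""
        return self.n_rows * self.sensel_pitch

    @property
    def sensel_area(self) -> float:
        """Area (m^2) of one sensel, taken as pitch^2 (square tiling)."""
        return self.sensel_pitch**2

    @classmethod
    def paper_mat(cls) -> "MatGeometry":
        """High-resolution walkway preset: 4 sensels/cm^2, 30 frames/s.

        A 1.95 m x 0.45 m walkway at 4 sensels/cm^2 gives a 0.005 m
        pitch and a 390 x 90 grid (35,100 sensels; vendor literature for
        comparable mats quotes slightly smaller active counts).
        """
        return cls(n_rows=90, n_cols=390, sensel_pitch=0.005, frame_rate=30.0)


@dataclass
class PressureRecording:
    """One continuous walking pass recorded on a pressure mat.

    ``frames`` is a ``(n_frames, n_rows, n_cols)`` array of non-negative
    pressures in kPa; ``timestamps`` are seconds, uniformly spaced at
    ``1 / frame_rate``.
    """

    geometry: MatGeometry
    frames: np.ndarray
    timestamps: np.ndarray
    subject_id: str = ""
    state_label: str = ""
    session_id: str = ""
    pass_id: str = ""
    calibration_weight: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise FrameDimensionError("frames must be a 3-D array")
        n_frames, n_rows, n_cols = self.frames.shape
        if (n_rows, n_cols) != (self.geometry.n_rows, self.geometry.n_cols):
            raise FrameDimensionError(
                f"frame grid {n_rows}x{n_cols} does not match geometry "
                f"{self.geometry.n_rows}x{self.geometry.n_cols}"
            )
        if self.timestamps.shape != (n_frames,):
            raise FormatError("timestamps must align with frames")
        if n_frames and np.min(self.frames) < 0:
            raise FormatError("pressures must be non-negative")
        if n_frames > 1:
            steps = np.diff(self.timestamps)
            expected = 1.0 / self.geometry.frame_rate
            if np.any(steps <= 0) or np.max(np.abs(steps - expected)) > _TIMESTAMP_TOL:
                raise FormatError(
                    "timestamps must increase in constant steps of 1/frame_rate"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Elapsed time (s) between the first and last frame."""
        if self.n_frames < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


def pressure_to_force(
    frame: np.ndarray,
    geometry: MatGeometry,
    mask: np.ndarray | None = None,
) -> float:
    """Aggregate a pressure grid (kPa) into a force in kilogram-force.

    ``force = sum(p_i * 1000 * pitch^2) / g0`` over the selected sensels,
    with g0 the standard gravity.  ``mask`` is an optional boolean grid
    or integer index selecting a sensel subset (e.g. one strike box).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (geometry.n_rows, geometry.n_cols):
        raise FrameDimensionError(
            f"frame shape {frame.shape} does not match geometry"
        )
    if mask is None:
        total = float(frame.sum())
    else:
        total = float(frame[mask].sum())  # numpy raises IndexError if outside
    return total * 1000.0 * geometry.sensel_area / STANDARD_GRAVITY


def frame_forces(recording: PressureRecording) -> np.ndarray:
    """Whole-mat force (kgf) per frame."""
    sums = recording.frames.reshape(recording.n_frames, -1).sum(axis=1)
    return sums * 1000.0 * recording.geometry.sensel_area / STANDARD_GRAVITY


def calibrate_to_weight(
    recording: PressureRecording,
    subject_weight: float,
    window: tuple[int, int],
) -> PressureRecording:
    """Rescale pressures so mean whole-mat force over ``window`` equals
    the subject's weight.

    ``window`` is an inclusive ``(first_frame, last_frame)`` range during
    which the subject stands quietly with full support on the mat.  The
    scale factor is recorded in ``metadata["calibration_scale"]``.
    """
    if subject_weight <= 0:
        raise CalibrationError("subject_weight must be > 0")
    lo, hi = window
    if not (0 <= lo <= hi < recording.n_frames):
        raise CalibrationError(f"window {window} outside recording")
    forces = frame_forces(recording)[lo : hi + 1]
    mean_force = float(forces.mean())
    if mean_force <= 0:
        raise CalibrationError("zero-force calibration window")
    scale = subject_weight / mean_force
    out = replace(
        recording,
        frames=recording.frames * scale,
        calibration_weight=subject_weight,
        metadata={**recording.metadata, "calibration_scale": scale},
    )
    return out


# ---------------------------------------------------------------------------
# .pwm dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = (
    "n_rows",
    "n_cols",
    "sensel_pitch_m",
    "frame_rate_hz",
    "subject_id",
    "state_label",
    "session_id",
    "pass_id",
)


def write_recording(recording: PressureRecording, path) -> None:
    """Write a recording in the plain-text ``.pwm`` dialect.

    Header lines are ``key = value``; each frame is a ``FRAME <index>
    <timestamp_s>`` line followed by ``n_rows`` rows of ``n_cols``
    space-separated pressures (kPa), printed with 6 significant digits.
    Zero-frame recordings are unwritable.
    """
    if recording.n_frames == 0:
        raise FormatError("cannot write a zero-frame recording")
    g = recording.geometry
    buf = io.StringIO()
    buf.write(f"n_rows = {g.n_rows}\n")
    buf.write(f"n_cols = {g.n_cols}\n")
    buf.write(f"sensel_pitch_m = {g.sensel_pitch!r}\n")
    buf.write(f"frame_rate_hz = {g.frame_rate!r}\n")
    buf.write(f"subject_id = {recording.subject_id}\n")
    buf.write(f"state_label = {recording.state_label}\n")
    buf.write(f"session_id = {recording.session_id}\n")
    buf.write(f"pass_id = {recording.pass_id}\n")
    if recording.calibration_weight is not None:
        buf.write(f"calibration_weight_kgf = {recording.calibration_weight!r}\n")
    for idx in range(recording.n_frames):
        buf.write(f"FRAME {idx} {float(recording.timestamps[idx])!r}\n")
        for row in recording.frames[idx]:
            buf.write(" ".join(f"{v:.6g}" for v in row))
            buf.write("\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_recording(path, geometry_override: MatGeometry | None = None) -> PressureRecording:
    """Read a ``.pwm`` file written by :func:`write_recording`.

    ``geometry_override`` replaces the header geometry (grid dimensions
    must still match the frame blocks).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    header: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if line.startswith("FRAME"):
            break
        if not line.strip():
            continue
        if "=" not in line:
            raise FormatError(f"malformed header line {i + 1}: {line!r}")
        key, _, value = line.partition("=")
        header[key.strip()] = value.strip()
    else:
        raise FormatError("no FRAME blocks found")

    for key in ("n_rows", "n_cols", "sensel_pitch_m", "frame_rate_hz"):
        if key not in header:
            raise FormatError(f"missing header key {key!r}")
    try:
        geometry = MatGeometry(
            n_rows=int(header["n_rows"]),
            n_cols=int(header["n_cols"]),
            sensel_pitch=float(header["sensel_pitch_m"]),
            frame_rate=float(header["frame_rate_hz"]),
        )
    except ValueError as exc:
        raise FormatError(f"invalid geometry header: {exc}") from exc
    if geometry_override is not None:
        if (geometry_override.n_rows, geometry_override.n_cols) != (
            geometry.n_rows,
            geometry.n_cols,
        ):
            raise FrameDimensionError("geometry override grid does not match file")
        geometry = geometry_override

    calib = header.get("calibration_weight_kgf")

    frames: list[np.ndarray] = []
    timestamps: list[float] = []
    pos = i
    frame_no = 0
    while pos < len(lines):
        line = lines[pos]
        if not line.strip():
            pos += 1
            continue
        parts = line.split()
        if parts[0] != "FRAME" or len(parts) != 3:
            raise FormatError(f"expected FRAME line at line {pos + 1}: {line!r}")
        timestamps.append(float(parts[2]))
        pos += 1
        grid = []
        for r in range(geometry.n_rows):
            if pos >= len(lines):
                raise FrameDimensionError(
                    f"frame {frame_no}: truncated after {r} rows"
                )
            values = lines[pos].split()
            if len(values) != geometry.n_cols:
                raise FrameDimensionError(
                    f"frame {frame_no}: row {r} has {len(values)} values, "
                    f"expected {geometry.n_cols}"
                )
            grid.append([float(v) for v in values])
            pos += 1
        frames.append(np.array(grid, dtype=float))
        frame_no += 1

    return PressureRecording(
        geometry=geometry,
        frames=np.stack(frames),
        timestamps=np.array(timestamps),
        subject_id=header.get("subject_id", ""),
        state_label=header.get("state_label", ""),
        session_id=header.get("session_id", ""),
        pass_id=header.get("pass_id", ""),
        calibration_weight=float(calib) if calib is not None else None,
    )
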
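"""Spatiotemporal gait parameters from labeled strike boxes.

Per-stride quantities follow the standard strike-box construction: for
two consecutive contacts of one limb, let d1/d2 be the heel and toe
edges of the first box, d3 the heel edge of the next box (meters along
the travel axis, heel = trailing edge), and t1/t2/t3 the first-contact,
last-contact and next-first-contact times (seconds).  Then

* stance length = d2 - d1, swing length = d3 - d2, stride length = d3 - d1
* stance time = t2 - t1, swing time = t3 - t2, stride time = t3 - t1
* stride speed = stride length / stride time

so stride = stance + swing holds exactly in both distance and time.

Pass-level quantities use all retained boxes regardless of limb:
``dN`` spans the heel edge of the first box to the toe edge of the last,
``tN`` the first to the last instance of non-zero pressure, cadence is
``n_stances / tN * 60`` steps/min and gait speed ``dN / tN`` m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataQualityError, DegeneratePassError, IntegrityError, UsageError
from .footfall_detection import StrikeBox
from .walkway_io import PressureRecording

FRONT_LIMBS = {"LF", "RF"}

STRIDE_PARAMETERS = (
    ("stride_length", "m"),
    ("stance_length", "m"),
    ("swing_length", "m"),
    ("stride_time", "s"),
    ("stance_time", "s"),
    ("swing_time", "s"),
    ("stride_speed", "m/s"),
)

PASS_PARAMETERS = (("cadence", "steps/min"), ("gait_speed", "m/s"))

TABLE_COLUMNS = [
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
]


@dataclass(frozen=True)
class StrideRecord:
    """One stride cycle of one limb (see module docstring for symbols).

    Positions are stored in the travel-aligned coordinate (increasing in
    the walking direction) so all lengths are positive in a forward pass.
    """

    limb: str
    stride_index: int
    d1: float
    d2: float
    d3: float
    t1: float
    t2: float
    t3: float
    subject_id: str = ""
    state_label: str = ""
    session_id: str = ""
    pass_id: str = ""

    @property
    def stance_length(self) -> float:
        return self.d2 - self.d1

    @property
    def swing_length(self) -> float:
        return self.d3 - self.d2

    @property
    def stride_length(self) -> float:
        return self.d3 - self.d1

    @property
    def stance_time(self) -> float:
        return self.t2 - self.t1

    @property
    def swing_time(self) -> float:
        return self.t3 - self.t2

    @property
    def stride_time(self) -> float:
        return self.t3 - self.t1

    @property
    def stride_speed(self) -> float:
        return self.stride_length / self.stride_time

    @property
    def limb_group(self) -> str:
        return "front" if self.limb in FRONT_LIMBS else "hind"


@dataclass(frozen=True)
class PassSummary:
    """Whole-pass metrics over all retained strike boxes."""

    n_stances: int
    dN: float
    tN: float
    valid: bool = True
    subject_id: str = ""
    state_label: str = ""
    session_id: str = ""
    pass_id: str = ""

    def __post_init__(self) -> None:
        if self.tN <= 0:
            raise DegeneratePassError("pass duration tN must be > 0")

    @property
    def cadence(self) -> float:
        """Steps per minute across all limbs."""
        return self.n_stances / self.tN * 60.0

    @property
    def gait_speed(self) -> float:
        """Whole-pass translation speed (m/s)."""
        return self.dN / self.tN

    @property
    def cadence_reported(self) -> int:
        """Cadence rounded half-up to an integer, as conventionally printed."""
        return int(math.floor(self.cadence + 0.5))

    @property
    def gait_speed_reported(self) -> float:
        """Gait speed rounded to 2 decimals, as conventionally printed."""
        return round(self.gait_speed, 2)


def _signed_edges(box: StrikeBox, direction: int) -> tuple[float, float]:
    if box.heel_edge_x is None or box.toe_edge_x is None:
        raise UsageError("boxes must be direction-normalized (run detect_direction)")
    return direction * box.heel_edge_x, direction * box.toe_edge_x


def compute_stride_records(
    boxes: list[StrikeBox],
    direction: int = 1,
    metadata: dict | None = None,
) -> list[StrideRecord]:
    """Build one record per consecutive pair of same-limb boxes.

    ``boxes`` must all belong to one limb and be direction-normalized;
    they are processed in first-frame order.  Fewer than two boxes give
    an empty list.  Overlapping stances of one limb (non-positive swing
    time) indicate a segmentation failure and raise.
    """
    limbs = {b.limb for b in boxes}
    if len(limbs) > 1:
        raise UsageError(f"boxes span multiple limbs: {sorted(limbs)}")
    if len(boxes) < 2:
        return []
    meta = metadata or {}
    ordered = sorted(boxes, key=lambda b: b.first_frame)
    records = []
    for k, (a, b) in enumerate(zip(ordered, ordered[1:])):
        heel_a, toe_a = _signed_edges(a, direction)
        heel_b, _ = _signed_edges(b, direction)
        if b.first_time <= a.last_time:
            raise DataQualityError(
                f"overlapping stances of limb {a.limb}: boxes {a.box_id} and {b.box_id}"
            )
        records.append(
            StrideRecord(
                limb=a.limb,
                stride_index=k,
                d1=heel_a,
                d2=toe_a,
                d3=heel_b,
                t1=a.first_time,
                t2=a.last_time,
                t3=b.first_time,
                subject_id=meta.get("subject_id", ""),
                state_label=meta.get("state_label", ""),
                session_id=meta.get("session_id", ""),
                pass_id=meta.get("pass_id", ""),
            )
        )
    return records


def compute_pass_summary(
    boxes: list[StrikeBox],
    recording: PressureRecording | None = None,
    direction: int = 1,
    valid: bool = True,
    metadata: dict | None = None,
) -> PassSummary:
    """Cadence and gait speed of a pass from its retained boxes.

    The first box is the one with the earliest non-zero pressure, the
    last the one with the latest; ``dN`` runs from the first box's heel
    edge to the last box's toe edge.
    """
    if len(boxes) < 2:
        raise DegeneratePassError(
            "need >= 2 strike boxes for a pass summary (no heel-to-toe span)"
        )
    meta = metadata or {}
    if recording is not None:
        meta = {
            "subject_id": recording.subject_id,
            "state_label": recording.state_label,
            "session_id": recording.session_id,
            "pass_id": recording.pass_id,
            **meta,
        }
    first = min(boxes, key=lambda b: b.first_frame)
    last = max(boxes, key=lambda b: b.last_frame)
    t_n = last.last_time - first.first_time
    heel_first, _ = _signed_edges(first, direction)
    _, toe_last = _signed_edges(last, direction)
    return PassSummary(
        n_stances=len(boxes),
        dN=toe_last - heel_first,
        tN=t_n,
        valid=valid,
        subject_id=meta.get("subject_id", ""),
        state_label=meta.get("state_label", ""),
        session_id=meta.get("session_id", ""),
        pass_id=meta.get("pass_id", ""),
    )


def compute_interlimb_length(front_box: StrikeBox, hind_box: StrikeBox) -> float:
    """Distance (m) between the leading (toe) edges of an ipsilateral
    front/hind strike-box pair."""
    if front_box.limb not in FRONT_LIMBS:
        raise UsageError(f"{front_box.limb!r} is not a front limb")
    if hind_box.limb not in {"LH", "RH"}:
        raise UsageError(f"{hind_box.limb!r} is not a hind limb")
    if front_box.limb[0] != hind_box.limb[0]:
        raise UsageError("interlimb length requires an ipsilateral (same-side) pair")
    if front_box.toe_edge_x is None or hind_box.toe_edge_x is None:
        raise UsageError("boxes must be direction-normalized")
    return abs(front_box.toe_edge_x - hind_box.toe_edge_x)


def interlimb_lengths(boxes: list[StrikeBox]) -> list[dict]:
    """All ipsilateral interlimb lengths of a labeled pass.

    Each front box pairs with the same-side hind box whose first frame is
    nearest its own.
    """
    out = []
    for side in "LR":
        fronts = [b for b in boxes if b.limb == f"{side}F"]
        hinds = [b for b in boxes if b.limb == f"{side}H"]
        for fb in fronts:
            if not hinds:
                continue
            hb = min(hinds, key=lambda b: abs(b.first_frame - fb.first_frame))
            out.append(
                {
                    "side": side,
                    "front_box": fb.box_id,
                    "hind_box": hb.box_id,
                    "interlimb_length": compute_interlimb_length(fb, hb),
                }
            )
    return out


def build_parameter_table(
    stride_records: list[StrideRecord],
    pass_summaries: list[PassSummary],
) -> pd.DataFrame:
    """Long-format tidy table feeding the statistics stage.

    One row per (stride, parameter) for the stride-level quantities plus
    one row per (pass, parameter) for cadence and gait speed.  Duplicate
    (pass, limb, stride index, parameter) rows violate integrity.
    """
    rows = []
    for rec in stride_records:
        for param, unit in STRIDE_PARAMETERS:
            rows.append(
                (
                    rec.subject_id,
                    rec.state_label,
                    rec.session_id,
                    rec.pass_id,
                    rec.limb,
                    rec.limb_group,
                    rec.stride_index,
                    param,
                    getattr(rec, param),
                    unit,
                )
            )
    for summary in pass_summaries:
        for param, unit in PASS_PARAMETERS:
            rows.append(
                (
                    summary.subject_id,
                    summary.state_label,
                    summary.session_id,
                    summary.pass_id,
                    "all",
                    "all",
                    0,
                    param,
                    getattr(summary, param),
                    unit,
                )
            )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if len(table):
        key = ["pass", "limb", "stride_index", "parameter"]
        if table.duplicated(subset=key).any():
            dup = table[table.duplicated(subset=key)].iloc[0]
            raise IntegrityError(
                f"duplicate parameter row for pass={dup['pass']!r} "
                f"limb={dup['limb']!r} stride={dup['stride_index']}"
            )
    return table
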
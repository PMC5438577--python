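"""Segment angles, landmark angles and spatiotemporal gait parameters.

Segment angles are sagittal-plane angles between a body segment line and
the vertical: 0 deg when the segment is perpendicular to the ground,
positive counter-clockwise (proximal end leaning forward when +x is the
direction of progression), negative clockwise.  These are segment angles,
not joint angles — each segment is measured against the room, not against
the adjacent segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateGeometryError, FormatError, InsufficientCyclesError
from .preprocess import Events
from .trial_io import SEGMENTS, Trial

#: minimum peak prominence (deg) for the foot's two gait peaks
PEAK_PROMINENCE = 1.0

#: marker names used by the spatiotemporal computation
SPATIOTEMPORAL_MARKERS = ("sacrum", "heel_r", "heel_l")


@dataclass
class SegmentAngleSeries:
    segment: str
    theta: np.ndarray  # degrees

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.segment not in SEGMENTS:
            raise FormatError(f"unknown segment {self.segment!r}")
        if not np.all(np.isfinite(self.theta)):
            raise FormatError("segment angle contains non-finite values")
        if np.any(np.abs(self.theta) > 180.0):
            raise FormatError("segment angle exceeds +/-180 deg")


@dataclass
class AngleLandmarks:
    """Landmark values of one normalised angle curve.

    Fields that do not apply to a segment/task combination are ``None``
    (the shank has no gait maximum of interest; only the foot has the two
    gait peaks).  ``flags`` records required landmarks that could not be
    found, without failing the trial.
    """

    initial: float
    min: float | None = None
    max: float | None = None
    first_peak: float | None = None
    second_peak: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class SpatiotemporalSummary:
    velocity: float  # cm/s
    cadence: float  # steps/min
    step_width: float  # cm
    stride_length: float  # cm
    stance_pct: float
    swing_pct: float
    stance_time_s: float


def compute_segment_angle(
    proximal: np.ndarray, distal: np.ndarray, segment: str
) -> SegmentAngleSeries:
    """Signed sagittal angle of the distal->proximal line from vertical.

    ``proximal``/``distal`` are (n, 2) arrays of sagittal (x, z) marker
    positions.  theta = atan2(dx, dz) in degrees, so a vertical segment is
    0 deg and a forward lean of the proximal end is positive.
    """
    proximal = np.atleast_2d(np.asarray(proximal, dtype=float))
    distal = np.atleast_2d(np.asarray(distal, dtype=float))
    if proximal.shape != distal.shape or proximal.shape[1] != 2:
        raise FormatError("proximal and distal must be (n, 2) arrays of equal length")
    d = proximal - distal
    norms = np.hypot(d[:, 0], d[:, 1])
    if np.any(norms < 1e-9):
        bad = int(np.flatnonzero(norms < 1e-9)[0])
        raise DegenerateGeometryError(
            f"coincident markers at sample {bad}: segment direction undefined"
        )
    theta = np.degrees(np.arctan2(d[:, 0], d[:, 1]))
    return SegmentAngleSeries(segment, theta)


def _applicable(segment: str, task: str) -> set[str]:
    if task == "hop":
        return {"initial", "min", "max"}
    if segment == "foot":
        return {"initial", "min", "first_peak", "second_peak"}
    return {"initial", "min"}


def extract_landmarks(theta: np.ndarray, segment: str, task: str) -> AngleLandmarks:
    """Landmarks of a normalised-cycle angle curve.

    ``initial`` is the value at cycle start; ``min``/``max`` are global
    extrema; for the foot during gait the two peaks are the highest local
    maxima (prominence >= 1 deg) in the first and second halves of the
    cycle.  A missing required peak is flagged, not fatal.
    """
    theta = np.asarray(theta, dtype=float)
    wanted = _applicable(segment, task)
    lm = AngleLandmarks(initial=float(theta[0]))
    if "min" in wanted:
        lm.min = float(np.min(theta))
    if "max" in wanted:
        lm.max = float(np.max(theta))
    if "first_peak" in wanted or "second_peak" in wanted:
        peaks, props = find_peaks(theta, prominence=PEAK_PROMINENCE)
        half = (theta.size - 1) / 2.0
        early = peaks[peaks < half]
        late = peaks[peaks >= half]
        if early.size:
            lm.first_peak = float(np.max(theta[early]))
        else:
            lm.flags.append("first_peak_missing")
        if late.size:
            lm.second_peak = float(np.max(theta[late]))
        else:
            lm.flags.append("second_peak_missing")
    return lm


def _first_cycle(events: Events) -> tuple[int, int, int]:
    ics = events.initial_contacts
    if ics.size < 2:
        raise InsufficientCyclesError("need two initial contacts for a gait cycle")
    ic1, ic2 = int(ics[0]), int(ics[1])
    tos = [int(t) for t in events.toe_offs if ic1 < t < ic2]
    if not tos:
        raise InsufficientCyclesError("no toe-off inside the first gait cycle")
    return ic1, tos[0], ic2


def compute_spatiotemporal(
    trial: Trial, events: Events, side: str = "r"
) -> SpatiotemporalSummary:
    """Spatiotemporal parameters of the first complete gait cycle.

    Velocity is the sacrum's forward displacement over the cycle divided
    by its duration; stride length is the forward distance travelled by
    the ipsilateral heel between successive initial contacts; cadence
    assumes symmetric steps (two steps per cycle); step width is the
    mediolateral heel separation at the two sides' contacts (the
    contralateral contact approximated at mid-cycle, where the force
    plate only instruments one limb).  Lengths are reported in cm.
    """
    missing = [m for m in SPATIOTEMPORAL_MARKERS if m not in trial.markers]
    if missing:
        raise FormatError(f"missing markers for spatiotemporal analysis: {missing}")
    ic1, to, ic2 = _first_cycle(events)
    t = trial.time
    cycle_s = float(t[ic2] - t[ic1])
    sacrum = trial.markers["sacrum"]
    heel_ips = trial.markers[f"heel_{side}"]
    heel_con = trial.markers["heel_l" if side == "r" else "heel_r"]
    velocity = (sacrum[ic2, 0] - sacrum[ic1, 0]) / cycle_s * 100.0
    stride = (heel_ips[ic2, 0] - heel_ips[ic1, 0]) * 100.0
    cadence = 120.0 / cycle_s
    ic_con = (ic1 + ic2) // 2  # contralateral contact ~ mid-cycle
    step_width = abs(heel_ips[ic1, 1] - heel_con[ic_con, 1]) * 100.0
    stance_pct = (to - ic1) / (ic2 - ic1) * 100.0
    return SpatiotemporalSummary(
        velocity=float(velocity),
        cadence=float(cadence),
        step_width=float(step_width),
        stride_length=float(stride),
        stance_pct=float(stance_pct),
        swing_pct=100.0 - float(stance_pct),
        stance_time_s=float(t[to] - t[ic1]),
    )
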
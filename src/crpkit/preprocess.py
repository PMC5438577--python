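"""Smoothing, contact-event detection, phase segmentation, time normalisation.

The path from raw channels to analysable cycles: zero-lag Butterworth
low-pass smoothing of kinematic channels, threshold detection of foot
contact from the vertical ground-reaction force, definition of the
movement-phase windows (stance/swing for gait; preflight/flight/landing
for the one-leg hop) on the normalised 0-100% time base, and cubic-spline
interpolation of any channel onto that base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .errors import (
    EventDetectionError,
    EventOrderingError,
    FilterError,
    InsufficientCyclesError,
    InterpolationError,
)

#: minimum contact-run duration (s); shorter runs are treated as noise
DEBOUNCE_S = 0.025

#: angular speed (deg/s) above which a hop trial is considered under way
HOP_ONSET_SPEED = 5.0

GAIT_PHASES = ("stance", "swing")
HOP_PHASES = ("preflight", "flight", "landing")


@dataclass
class Events:
    """Detected initial contacts and toe-offs, as raw sample indices."""

    task: str
    initial_contacts: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.initial_contacts = np.asarray(self.initial_contacts, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)


@dataclass
class PhaseWindows:
    """Half-open index intervals partitioning the normalised time base."""

    task: str
    windows: dict[str, tuple[int, int]]

    def names(self) -> tuple[str, ...]:
        return tuple(self.windows)

    def n_points(self) -> int:
        return max(b for _, b in self.windows.values())


def baseline_correct_grf(grf: np.ndarray) -> np.ndarray:
    """Remove the plate offset: subtract the median of the lowest decile
    of samples and clamp at zero."""
    grf = np.asarray(grf, dtype=float)
    k = max(1, int(np.ceil(grf.size / 10)))
    baseline = float(np.median(np.sort(grf)[:k]))
    return np.clip(grf - baseline, 0.0, None)


def lowpass_filter(
    x: np.ndarray, fs: float, cutoff: float = 6.0, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    ``order`` is the order of each pass; the double pass squares the
    magnitude response, so the gain at the cutoff frequency is 0.5.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2.0:
        raise FilterError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    if x.size < 3 * order:
        raise FilterError(
            f"series of length {x.size} too short for an order-{order} filter"
        )
    b, a = butter(order, cutoff, btype="low", fs=fs)
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    return filtfilt(b, a, x, padlen=padlen)


def _contact_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as half-open (start, stop) pairs,
    dropping runs shorter than ``min_len`` samples."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_len]


def detect_contact_events(
    grf: np.ndarray, threshold: float, task: str, fs: float
) -> Events:
    """Threshold detection of initial contact (IC) and toe-off (TO).

    IC is the first sample of each maximal run with ``grf >= threshold``;
    TO is the first sample after such a run.  Runs shorter than 25 ms are
    ignored (debounce).  For a hop the events reduce to the single take-off
    TO followed by the landing IC.  ``task="generic"`` returns all runs
    without task-specific checks.
    """
    grf = np.asarray(grf, dtype=float)
    min_len = max(1, int(round(DEBOUNCE_S * fs)))
    runs = _contact_runs(grf >= threshold, min_len)
    if not runs:
        raise EventDetectionError("no contact detected")
    ics = [a for a, _ in runs]
    tos = [b for _, b in runs if b < grf.size]  # a run ending at the last
    # sample has no observed toe-off
    if task == "generic":
        return Events(task, np.array(ics), np.array(tos))
    if task == "gait":
        if len(ics) < 2:
            raise InsufficientCyclesError(
                f"gait trial needs >= 2 initial contacts, found {len(ics)}"
            )
        return Events(task, np.array(ics), np.array(tos))
    if task == "hop":
        # take-off = first toe-off; landing = first IC after it
        if not tos:
            raise EventDetectionError("hop trial: no take-off detected")
        to = tos[0]
        later = [ic for ic in ics if ic > to]
        if not later:
            raise EventDetectionError("hop trial: no landing contact after take-off")
        return Events(task, np.array([later[0]]), np.array([to]))
    raise EventDetectionError(f"unknown task {task!r}")


def hop_analysis_start(
    angles: dict[str, np.ndarray], fs: float, speed_threshold: float = HOP_ONSET_SPEED
) -> int:
    """First sample where any segment's angular speed exceeds the threshold
    (deg/s); falls back to the trial start if none does."""
    speeds = [np.abs(np.gradient(a, 1.0 / fs)) for a in angles.values()]
    any_fast = np.any(np.vstack(speeds) > speed_threshold, axis=0)
    idx = np.flatnonzero(any_fast)
    return int(idx[0]) if idx.size else 0


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _to_grid(idx: int, span: tuple[int, int], n_points: int) -> int:
    a, b = span
    pct = (idx - a) / (b - a) * 100.0
    return _round_half_up(pct * (n_points - 1) / 100.0)


def define_phase_windows(
    events: Events, span: tuple[int, int], task: str, n_points: int = 101
) -> PhaseWindows:
    """Map contact events to half-open windows on the 0-100% grid.

    ``span`` is the (start, end) raw-index interval (inclusive endpoints)
    that the normalised base covers: for gait IC1..IC2, for a hop the
    analysis start..end.  Percent boundaries land on the grid by
    round-half-up.  The windows partition ``[0, n_points)``.
    """
    a, b = span
    if b <= a:
        raise EventOrderingError("empty analysis span")
    if task == "gait":
        tos = [t for t in events.toe_offs if a < t < b]
        if not tos:
            raise EventOrderingError("toe-off not inside the gait cycle (IC1, IC2)")
        i_to = _to_grid(int(tos[0]), span, n_points)
        windows = {"stance": (0, i_to), "swing": (i_to, n_points)}
    elif task == "hop":
        to = int(events.toe_offs[0])
        ic = int(events.initial_contacts[0])
        if not (a < to < ic < b + 1):
            raise EventOrderingError("hop events must satisfy start < TO < IC <= end")
        i_to = _to_grid(to, span, n_points)
        i_ic = _to_grid(ic, span, n_points)
        windows = {
            "preflight": (0, i_to),
            "flight": (i_to, i_ic),
            "landing": (i_ic, n_points),
        }
    else:
        raise EventOrderingError(f"unknown task {task!r}")
    for name, (lo, hi) in windows.items():
        if hi - lo < 2:
            raise EventOrderingError(
                f"phase window {name!r} spans {hi - lo} grid points (< 2)"
            )
    return PhaseWindows(task, windows)


def time_normalize(
    x: np.ndarray, span: tuple[int, int], n_points: int = 101
) -> np.ndarray:
    """Cubic-spline interpolation of ``x[span[0]..span[1]]`` (inclusive)
    onto ``n_points`` equally spaced points; endpoints preserved exactly."""
    x = np.asarray(x, dtype=float)
    a, b = span
    if b - a + 1 < 4:
        raise InterpolationError(f"span of {b - a + 1} samples too short to normalise")
    idx = np.arange(a, b + 1)
    spline = CubicSpline(idx, x[a : b + 1])
    grid = np.linspace(a, b, n_points)
    out = spline(grid)
    out[0] = x[a]
    out[-1] = x[b]
    return out
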
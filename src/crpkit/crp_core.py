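"""Continuous relative phase: portraits, phase angles, CRP, per-phase summaries.

For each segment the phase portrait plots the amplitude-normalised
angular velocity (normV, y-axis) against the amplitude-normalised angle
(normtheta, x-axis), both rescaled to [-1, 1].  The phase angle is the
polar angle of the portrait, taken with the quadrant-aware two-argument
arctangent and unwrapped by multiples of 360 deg so the series is
continuous.  The continuous relative phase (CRP) of a segment couple is
the proximal phase minus the distal phase:

    CRP_TS = phi_thigh - phi_shank
    CRP_SF = phi_shank - phi_foot
    CRP_TF = phi_thigh - phi_foot

CRP near 0 deg means the two segments move in phase; values near 180 deg
mean anti-phase motion.  Coordination is summarised per movement phase
by the RMS of the ensemble-mean CRP curve (in-phase vs out-of-phase
index) and by the across-trials SD of the CRP averaged over the window
(coordinative variability, the deviation phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import CrpkitError, DegenerateSignalError, UndefinedPhaseError
from .preprocess import PhaseWindows

#: segment couples: name -> (proximal, distal)
COUPLES: dict[str, tuple[str, str]] = {
    "TS": ("thigh", "shank"),
    "SF": ("shank", "foot"),
    "TF": ("thigh", "foot"),
}


@dataclass
class PhasePortrait:
    """Normalised angle (x) and velocity (y), both in [-1, 1]."""

    norm_theta: np.ndarray
    norm_v: np.ndarray

    def __post_init__(self) -> None:
        self.norm_theta = np.asarray(self.norm_theta, dtype=float)
        self.norm_v = np.asarray(self.norm_v, dtype=float)
        if self.norm_theta.shape != self.norm_v.shape:
            raise CrpkitError("portrait channels must share one length")


@dataclass
class PhaseAngleSeries:
    """Unwrapped phase angle in degrees (may exceed +/-180)."""

    phi: np.ndarray
    carried_forward: np.ndarray | None = None  # samples where (0,0) was patched

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)


@dataclass
class CRPSeries:
    couple: str
    crp: np.ndarray

    def __post_init__(self) -> None:
        if self.couple not in COUPLES:
            raise CrpkitError(f"unknown couple {self.couple!r}")
        self.crp = np.asarray(self.crp, dtype=float)


@dataclass
class PhaseSummary:
    couple: str
    phase: str
    rms: float
    sd: float
    n_trials: int


def compute_velocity(theta: np.ndarray, fs: float) -> np.ndarray:
    """Angular velocity in deg/s: central differences in the interior,
    one-sided differences at the two ends."""
    theta = np.asarray(theta, dtype=float)
    if theta.size < 3:
        raise CrpkitError("need at least 3 samples to differentiate")
    return np.gradient(theta, 1.0 / fs)


def normalize_amplitude(
    x: np.ndarray, scope: tuple[int, int] | None = None
) -> np.ndarray:
    """Min-max rescale of ``x`` to [-1, 1], extrema taken over ``scope``
    (half-open index interval; default the whole series)."""
    x = np.asarray(x, dtype=float)
    lo, hi = (0, x.size) if scope is None else scope
    seg = x[lo:hi]
    mn, mx = float(np.min(seg)), float(np.max(seg))
    if mx - mn <= 1e-12 * max(1.0, abs(mx)):
        raise DegenerateSignalError("constant signal: amplitude undefined")
    return 2.0 * (x - mn) / (mx - mn) - 1.0


def normalize_max_abs(x: np.ndarray, scope: tuple[int, int] | None = None) -> np.ndarray:
    """Alternative velocity normalisation: divide by the peak magnitude,
    preserving the zero crossing."""
    x = np.asarray(x, dtype=float)
    lo, hi = (0, x.size) if scope is None else scope
    m = float(np.max(np.abs(x[lo:hi])))
    if m <= 1e-12:
        raise DegenerateSignalError("zero signal: amplitude undefined")
    return x / m


def unwrap_degrees(phi_raw: np.ndarray) -> np.ndarray:
    """Add integer multiples of 360 deg so successive differences lie in
    (-180, 180]; the first sample is unchanged."""
    phi_raw = np.asarray(phi_raw, dtype=float)
    if phi_raw.size == 0:
        raise CrpkitError("cannot unwrap an empty series")
    d = np.diff(phi_raw)
    adj = d - 360.0 * np.ceil((d - 180.0) / 360.0)
    return np.concatenate(([phi_raw[0]], phi_raw[0] + np.cumsum(adj)))


def compute_phase_angle(portrait: PhasePortrait) -> PhaseAngleSeries:
    """Unwrapped polar angle of the phase portrait, degrees.

    phi_raw = atan2(normV, normtheta) in (-180, 180]; a (0, 0) sample
    has no phase — its value is carried forward from the previous sample
    and flagged; (0, 0) at the first sample is an error.
    """
    th, v = portrait.norm_theta, portrait.norm_v
    degenerate = (np.abs(th) < 1e-12) & (np.abs(v) < 1e-12)
    if degenerate[0]:
        raise UndefinedPhaseError("phase undefined at the first sample (origin)")
    phi_raw = np.degrees(np.arctan2(v, th))
    phi_raw[phi_raw == -180.0] = 180.0
    if degenerate.any():
        for i in np.flatnonzero(degenerate):
            phi_raw[i] = phi_raw[i - 1]
    return PhaseAngleSeries(
        phi=unwrap_degrees(phi_raw),
        carried_forward=degenerate if degenerate.any() else None,
    )


def compute_crp(
    phi_prox: PhaseAngleSeries, phi_dist: PhaseAngleSeries, couple: str
) -> CRPSeries:
    """CRP curve: phase of the distal segment subtracted from the phase
    of the proximal segment, pointwise."""
    if phi_prox.phi.shape != phi_dist.phi.shape:
        raise CrpkitError("phase series lengths differ")
    return CRPSeries(couple, phi_prox.phi - phi_dist.phi)


def summarize_crp(
    curves_by_couple: Mapping[str, Sequence[np.ndarray]],
    windows: PhaseWindows,
    sd_mode: str = "across_trials",
    rms_mode: str = "ensemble",
) -> list[PhaseSummary]:
    """Per-phase RMS and SD of the CRP over the trials of one
    subject x task x condition cell.

    RMS (``ensemble`` mode) is the root mean square of the across-trials
    ensemble-mean CRP curve within the window; ``per_trial`` averages the
    per-trial RMS instead.  SD in ``across_trials`` mode is the per-point
    sample SD across trials averaged over the window (deviation phase,
    needs >= 2 trials); ``within_curve`` is the SD of the mean curve's
    own points within the window.
    """
    out: list[PhaseSummary] = []
    for couple, curves in curves_by_couple.items():
        stack = np.vstack([np.asarray(c, dtype=float) for c in curves])
        n_trials = stack.shape[0]
        mean_curve = stack.mean(axis=0)
        if sd_mode == "across_trials" and n_trials < 2:
            raise CrpkitError(
                "across_trials SD needs >= 2 trials; use sd_mode='within_curve'"
            )
        for phase, (lo, hi) in windows.windows.items():
            pts = mean_curve[lo:hi]
            if rms_mode == "ensemble":
                rms = float(np.sqrt(np.mean(pts**2)))
            else:
                rms = float(np.mean(np.sqrt(np.mean(stack[:, lo:hi] ** 2, axis=1))))
            if sd_mode == "across_trials":
                sd = float(np.mean(np.std(stack[:, lo:hi], axis=0, ddof=1)))
            else:
                sd = float(np.std(pts, ddof=1))
            out.append(PhaseSummary(couple, phase, rms, sd, n_trials))
    return out
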
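"""End-to-end per-trial analysis: raw channels -> phase angles, CRP curves,
phase windows, landmarks and spatiotemporal parameters.

Order of operations: the ground-reaction force is baseline-corrected and
contact events detected; segment angles are low-pass filtered; angular
velocity is computed on the real time base and only then interpolated,
together with the angle, onto the normalised 0-100% base; both channels
are amplitude-normalised over the configured scope; phase angles are
unwrapped and differenced into CRP curves per segment couple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import crp_core, kinematics, preprocess
from .errors import CrpkitError
from .trial_io import SEGMENTS, RunConfig, Trial


@dataclass
class TrialResult:
    """Everything the pipeline derives from one trial."""

    trial: Trial
    events: preprocess.Events
    span: tuple[int, int]  # raw-sample span of the analysed cycle/hop
    windows: preprocess.PhaseWindows
    theta_norm: dict[str, np.ndarray]  # normalised-time angle curves (deg)
    phi: dict[str, crp_core.PhaseAngleSeries]
    crp: dict[str, crp_core.CRPSeries]
    landmarks: dict[str, kinematics.AngleLandmarks]
    spatiotemporal: kinematics.SpatiotemporalSummary | None

    def crp_curves(self) -> dict[str, np.ndarray]:
        return {c: s.crp for c, s in self.crp.items()}


def _analysis_span(
    trial: Trial,
    events: preprocess.Events,
    filtered: dict[str, np.ndarray],
    cycle: int = 0,
) -> tuple[int, int]:
    if trial.task == "gait":
        ics = events.initial_contacts
        if cycle + 1 >= ics.size:
            raise CrpkitError(
                f"trial has {ics.size - 1} complete cycles; cycle {cycle} requested"
            )
        return int(ics[cycle]), int(ics[cycle + 1])
    start = preprocess.hop_analysis_start(filtered, trial.fs)
    return start, trial.n_samples - 1


def n_complete_cycles(trial: Trial, events: preprocess.Events) -> int:
    """Number of analysable spans: IC-to-IC cycles for gait, 1 for a hop."""
    if trial.task == "hop":
        return 1
    return int(events.initial_contacts.size) - 1


def _normalize_pair(
    theta_n: np.ndarray,
    v_n: np.ndarray,
    windows: preprocess.PhaseWindows,
    config: RunConfig,
) -> crp_core.PhasePortrait:
    v_norm_fn = (
        crp_core.normalize_amplitude
        if config.velocity_normalization == "min_max"
        else crp_core.normalize_max_abs
    )
    if config.normalization_scope == "whole_cycle":
        return crp_core.PhasePortrait(
            crp_core.normalize_amplitude(theta_n), v_norm_fn(v_n)
        )
    nt = np.empty_like(theta_n)
    nv = np.empty_like(v_n)
    for lo, hi in windows.windows.values():
        hi_ = min(hi, theta_n.size)
        nt[lo:hi_] = crp_core.normalize_amplitude(theta_n, (lo, hi_))[lo:hi_]
        nv[lo:hi_] = v_norm_fn(v_n, (lo, hi_))[lo:hi_]
    return crp_core.PhasePortrait(nt, nv)


def analyze_trial(
    trial: Trial, config: RunConfig | None = None, cycle: int = 0
) -> TrialResult:
    """Run the full coordination analysis on one validated trial.

    For gait the analysed span is one complete cycle (initial contact to
    the next ipsilateral initial contact; ``cycle`` selects which, default
    the first); for a hop it runs from movement onset to the end of the
    recording.  :func:`analyze_all_cycles` analyses every recorded cycle.
    """
    config = config or RunConfig()
    trial.validate()
    config.check_against_fs(trial.fs)
    if not all(s in trial.angles for s in SEGMENTS):
        raise CrpkitError(
            "trial must carry thigh, shank and foot angle channels "
            "(compute them from markers first)"
        )
    grf = preprocess.baseline_correct_grf(trial.grf_vertical)
    events = preprocess.detect_contact_events(
        grf, config.grf_threshold_n, trial.task, trial.fs
    )
    filtered = {
        s: preprocess.lowpass_filter(
            trial.angles[s], trial.fs, config.cutoff_hz, config.filter_order
        )
        for s in SEGMENTS
    }
    span = _analysis_span(trial, events, filtered, cycle)
    windows = preprocess.define_phase_windows(events, span, trial.task, config.n_points)

    theta_norm: dict[str, np.ndarray] = {}
    phi: dict[str, crp_core.PhaseAngleSeries] = {}
    for seg in SEGMENTS:
        v = crp_core.compute_velocity(filtered[seg], trial.fs)
        theta_n = preprocess.time_normalize(filtered[seg], span, config.n_points)
        v_n = preprocess.time_normalize(v, span, config.n_points)
        portrait = _normalize_pair(theta_n, v_n, windows, config)
        theta_norm[seg] = theta_n
        phi[seg] = crp_core.compute_phase_angle(portrait)

    crp = {
        couple: crp_core.compute_crp(phi[prox], phi[dist], couple)
        for couple, (prox, dist) in crp_core.COUPLES.items()
    }
    landmarks = {
        seg: kinematics.extract_landmarks(theta_norm[seg], seg, trial.task)
        for seg in SEGMENTS
    }
    spatiotemporal = None
    if trial.task == "gait" and all(
        m in trial.markers for m in kinematics.SPATIOTEMPORAL_MARKERS
    ):
        spatiotemporal = kinematics.compute_spatiotemporal(trial, events)
    return TrialResult(
        trial=trial,
        events=events,
        span=span,
        windows=windows,
        theta_norm=theta_norm,
        phi=phi,
        crp=crp,
        landmarks=landmarks,
        spatiotemporal=spatiotemporal,
    )


def analyze_all_cycles(
    trial: Trial, config: RunConfig | None = None
) -> list[TrialResult]:
    """Analyse every complete cycle the trial contains.

    A gait recording with k+1 initial contacts holds k complete cycles;
    each becomes its own normalised curve, so the across-cycles ensemble
    uses all recorded strides rather than only the first.  A hop yields
    a single result.
    """
    config = config or RunConfig()
    first = analyze_trial(trial, config, cycle=0)
    if trial.task == "hop":
        return [first]
    results = [first]
    for k in range(1, n_complete_cycles(trial, first.events)):
        results.append(analyze_trial(trial, config, cycle=k))
    return results


def summarize_cell(
    results: list[TrialResult], config: RunConfig | None = None
) -> list[crp_core.PhaseSummary]:
    """Per-phase RMS/SD summaries over the trials of one
    subject x task x condition cell (all trials share a task)."""
    config = config or RunConfig()
    if not results:
        raise CrpkitError("no trials to summarise")
    tasks = {r.trial.task for r in results}
    if len(tasks) > 1:
        raise CrpkitError(f"cannot pool trials across tasks {sorted(tasks)}")
    curves = {
        couple: [r.crp[couple].crp for r in results] for couple in crp_core.COUPLES
    }
    return crp_core.summarize_crp(
        curves, results[0].windows, sd_mode=config.sd_mode, rms_mode=config.rms_mode
    )
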
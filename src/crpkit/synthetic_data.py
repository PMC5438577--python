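"""Synthetic gait and one-leg-hop trials with known ground truth.

The generator emulates the study conditions the pipeline expects: 120 Hz
sampling, sinusoidal segment-angle curves with segment-specific offsets
and amplitudes, inter-segment phase lags (the quantity the CRP recovers),
per-cycle phase jitter (which drives across-trials CRP variability),
additive white measurement noise, a ground-reaction-force bump spanning
a configurable stance fraction of each gait cycle, and a hop profile
whose flight phase has exactly zero ground reaction force.

Sinusoidal base curves were chosen over gait-template splines because
they make the CRP ground truth analytic: for pure sinusoids with phase
offsets b_seg, the CRP of a couple equals the distal base phase minus
the proximal base phase, so an imposed lag is recovered exactly up to
discretisation.  A harmonics option adds higher-frequency content for
realism tests without ground-truth claims.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import ConfigurationError
from .trial_io import SEGMENTS, Trial

#: gait defaults: amplitude/offset (deg) chosen so the curves span the
#: segment-angle ranges typical of level walking (thigh ~ +28..-15,
#: shank ~ +18..-59, foot ~ +82..+1)
GAIT_AMPLITUDES = {"thigh": 21.6, "shank": 38.5, "foot": 40.2}
GAIT_OFFSETS = {"thigh": 6.7, "shank": -20.7, "foot": 41.5}

#: hop defaults: ranges typical of a maximal one-leg hop
HOP_AMPLITUDES = {"thigh": 21.0, "shank": 24.0, "foot": 30.0}
HOP_OFFSETS = {"thigh": 16.0, "shank": -19.0, "foot": 50.0}


def _subject_key(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode()) & 0x7FFFFFFF


def _trial_rng(seed: int, subject_id: str, condition: str, trial_index: int, task: str):
    return np.random.default_rng(
        [
            int(seed),
            _subject_key(subject_id),
            0 if condition == "none" else 1,
            int(trial_index),
            0 if task == "gait" else 1,
        ]
    )


@dataclass
class GaitModel:
    """Parameters of a synthetic level-walking trial.

    Defaults reproduce an unimpaired adult walking at a self-selected
    speed: stride 1.47 m at 136 cm/s (cycle 1.081 s, cadence 111
    steps/min), 62% stance.  ``couple_lag_ts``/``couple_lag_sf`` are the
    thigh->shank and shank->foot phase lags in degrees; they are the CRP
    ground truth (CRP_TS = lag_ts, CRP_SF = lag_sf for noiseless input).
    ``jitter_sd`` is the SD of the per-cycle, per-segment constant phase
    perturbation (deg); ``noise_sd`` is white measurement noise (deg).
    """

    fs: float = 120.0
    n_cycles: int = 3
    cycle_duration: float = 1.47 / 1.36  # s; stride / walking speed
    stance_fraction: float = 0.62
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(GAIT_AMPLITUDES))
    offsets: dict[str, float] = field(default_factory=lambda: dict(GAIT_OFFSETS))
    couple_lag_ts: float = 40.0
    couple_lag_sf: float = 60.0
    jitter_sd: float = 5.0
    noise_sd: float = 0.5
    stride_length: float = 1.47  # m
    step_width: float = 0.12  # m
    grf_peak: float = 800.0  # N
    harmonics: tuple[tuple[int, float], ...] = ()  # (order, relative amplitude)
    seed: int = 0

    def validate(self) -> "GaitModel":
        if self.fs <= 0 or self.cycle_duration <= 0 or self.n_cycles < 1:
            raise ConfigurationError("fs, cycle_duration and n_cycles must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ConfigurationError("stance_fraction must lie in (0, 1)")
        if any(self.amplitudes[s] <= 0 for s in SEGMENTS):
            raise ConfigurationError("amplitudes must be positive")
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("jitter_sd and noise_sd must be >= 0")
        if self.stride_length <= 0 or self.grf_peak <= 0:
            raise ConfigurationError("stride_length and grf_peak must be positive")
        return self


@dataclass
class HopModel:
    """Parameters of a synthetic one-leg hop: ground contact (preflight),
    an airborne flight phase with zero ground reaction force, and landing."""

    fs: float = 120.0
    preflight_s: float = 0.5
    flight_s: float = 0.25
    landing_s: float = 0.5
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(HOP_AMPLITUDES))
    offsets: dict[str, float] = field(default_factory=lambda: dict(HOP_OFFSETS))
    couple_lag_ts: float = 40.0
    couple_lag_sf: float = 60.0
    jitter_sd: float = 5.0
    noise_sd: float = 0.5
    grf_peak: float = 1200.0  # N
    seed: int = 0

    def validate(self) -> "HopModel":
        if min(self.preflight_s, self.flight_s, self.landing_s) <= 0:
            raise ConfigurationError("hop phase durations must be positive")
        if self.fs <= 0 or self.grf_peak <= 0:
            raise ConfigurationError("fs and grf_peak must be positive")
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("jitter_sd and noise_sd must be >= 0")
        return self


def _base_phases(lag_ts: float, lag_sf: float) -> dict[str, float]:
    # CRP = phi_prox - phi_dist and phi = 90 deg - (omega t + b) for a
    # sinusoid, so CRP_TS = b_shank - b_thigh: the distal base phase must
    # LEAD by the imposed lag for the CRP to equal it.
    b_thigh = 0.0
    b_shank = b_thigh + np.radians(lag_ts)
    b_foot = b_shank + np.radians(lag_sf)
    return {"thigh": b_thigh, "shank": b_shank, "foot": b_foot}


def _segment_curve(
    u: np.ndarray,
    amplitude: float,
    offset: float,
    harmonics: tuple[tuple[int, float], ...] = (),
) -> np.ndarray:
    theta = offset + amplitude * np.sin(u)
    for order, rel in harmonics:
        theta = theta + amplitude * rel * np.sin(order * u)
    return theta


def generate_gait_trial(
    model: GaitModel,
    condition: str = "none",
    trial_index: int = 0,
    subject_id: str = "S01",
) -> Trial:
    """One synthetic walking trial; a pure function of (model, metadata).

    The k-th cycle occupies t in [k*T, (k+1)*T) with the stance interval
    at its start, so initial contacts fall at cycle boundaries.  The GRF
    is a half-sine bump of height ``grf_peak`` spanning exactly the
    stance fraction of each cycle and zero elsewhere.  Sacrum and heel
    markers progress at the cycle-average speed stride/T, making stride
    length and walking velocity exactly recoverable.
    """
    model.validate()
    rng = _trial_rng(model.seed, subject_id, condition, trial_index, "gait")
    fs, T = model.fs, model.cycle_duration
    n = int(round(model.n_cycles * T * fs)) + 1
    t = np.arange(n) / fs
    omega = 2.0 * np.pi / T
    phases = _base_phases(model.couple_lag_ts, model.couple_lag_sf)
    cycle_idx = np.minimum((t / T).astype(int), model.n_cycles - 1)
    jitter = rng.normal(0.0, np.radians(model.jitter_sd), (model.n_cycles, 3))
    angles: dict[str, np.ndarray] = {}
    for j, seg in enumerate(SEGMENTS):
        u = omega * t + phases[seg] + jitter[cycle_idx, j]
        theta = _segment_curve(u, model.amplitudes[seg], model.offsets[seg], model.harmonics)
        theta = theta + rng.normal(0.0, model.noise_sd, n)
        angles[seg] = theta
    # GRF: half-sine over the stance fraction at the start of each cycle
    s = np.mod(t, T) / (model.stance_fraction * T)
    grf = np.where(s < 1.0, model.grf_peak * np.sin(np.pi * np.clip(s, 0.0, 1.0)), 0.0)
    grf[t >= model.n_cycles * T] = 0.0
    speed = model.stride_length / T
    sacrum = np.column_stack([speed * t, np.zeros(n), np.full(n, 1.0)])
    heel_r = np.column_stack(
        [speed * t, np.full(n, -model.step_width / 2), np.full(n, 0.05)]
    )
    heel_l = np.column_stack(
        [
            speed * t - model.stride_length / 2,
            np.full(n, model.step_width / 2),
            np.full(n, 0.05),
        ]
    )
    return Trial(
        subject_id=subject_id,
        task="gait",
        condition=condition,
        trial_index=trial_index,
        fs=fs,
        time=t,
        angles=angles,
        markers={"sacrum": sacrum, "heel_r": heel_r, "heel_l": heel_l},
        grf_vertical=grf,
    ).validate()


def generate_hop_trial(
    model: HopModel,
    condition: str = "none",
    trial_index: int = 0,
    subject_id: str = "S01",
) -> Trial:
    """One synthetic one-leg hop; a pure function of (model, metadata).

    Segment angles follow one continuous sinusoidal arc over the whole
    movement with a per-trial, per-segment phase perturbation; the GRF
    is a half-sine bump during preflight, exactly zero during flight,
    and a second bump during landing.
    """
    model.validate()
    rng = _trial_rng(model.seed, subject_id, condition, trial_index, "hop")
    fs = model.fs
    total = model.preflight_s + model.flight_s + model.landing_s
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs
    omega = 2.0 * np.pi / total
    phases = _base_phases(model.couple_lag_ts, model.couple_lag_sf)
    jitter = rng.normal(0.0, np.radians(model.jitter_sd), 3)
    angles: dict[str, np.ndarray] = {}
    for j, seg in enumerate(SEGMENTS):
        u = omega * t + phases[seg] + jitter[j]
        theta = _segment_curve(u, model.amplitudes[seg], model.offsets[seg])
        angles[seg] = theta + rng.normal(0.0, model.noise_sd, n)
    grf = np.zeros(n)
    pre = t < model.preflight_s
    grf[pre] = model.grf_peak * np.sin(np.pi * t[pre] / model.preflight_s)
    t_land = model.preflight_s + model.flight_s
    land = t >= t_land
    grf[land] = model.grf_peak * np.sin(
        np.pi * np.clip((t[land] - t_land) / model.landing_s, 0.0, 1.0)
    )
    return Trial(
        subject_id=subject_id,
        task="hop",
        condition=condition,
        trial_index=trial_index,
        fs=fs,
        time=t,
        angles=angles,
        markers={},
        grf_vertical=grf,
    ).validate()


_NUMERIC_MODEL_FIELDS = {
    f.name
    for f in fields(GaitModel)
    if f.type in ("float", "int")
} | {f.name for f in fields(HopModel) if f.type in ("float", "int")}


def generate_cohort(
    n_subjects: int,
    effect: dict[str, float] | None = None,
    gait_model: GaitModel | None = None,
    hop_model: HopModel | None = None,
    seed: int = 0,
    n_gait: int = 5,
    n_hop: int = 3,
    between_subject_lag_sd: float = 5.0,
) -> list[Trial]:
    """A synthetic study: ``n_subjects`` subjects, both conditions,
    ``n_gait`` walking and ``n_hop`` hop trials each.

    Subject-level phase lags are drawn around the cohort means with SD
    ``between_subject_lag_sd`` (deg).  ``effect`` maps numeric model
    parameters (e.g. ``couple_lag_ts``) to additive shifts applied in
    the sleeve condition only, giving a known injected effect for
    power/recovery testing.
    """
    if n_subjects < 3:
        raise ConfigurationError("need at least 3 subjects")
    effect = dict(effect or {})
    bad = set(effect) - _NUMERIC_MODEL_FIELDS
    if bad:
        raise ConfigurationError(f"unknown effect parameters: {sorted(bad)}")
    gait_model = (gait_model or GaitModel()).validate()
    hop_model = (hop_model or HopModel()).validate()
    rng = np.random.default_rng([int(seed), 0xC0807])
    trials: list[Trial] = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        lag_ts = gait_model.couple_lag_ts + rng.normal(0, between_subject_lag_sd)
        lag_sf = gait_model.couple_lag_sf + rng.normal(0, between_subject_lag_sd)
        # between-subject spatiotemporal spread typical of healthy adults
        stride = max(1.0, gait_model.stride_length + rng.normal(0.0, 0.102))
        speed = max(0.8, (gait_model.stride_length / gait_model.cycle_duration)
                    + rng.normal(0.0, 0.069))
        for condition in ("none", "sleeve"):
            shifts = effect if condition == "sleeve" else {}
            gm = replace(
                gait_model,
                couple_lag_ts=lag_ts + shifts.get("couple_lag_ts", 0.0),
                couple_lag_sf=lag_sf + shifts.get("couple_lag_sf", 0.0),
                stride_length=stride,
                cycle_duration=stride / speed,
                seed=int(seed),
            )
            for key, shift in shifts.items():
                if key not in ("couple_lag_ts", "couple_lag_sf") and hasattr(gm, key):
                    gm = replace(gm, **{key: getattr(gm, key) + shift})
            hm = replace(
                hop_model,
                couple_lag_ts=lag_ts + shifts.get("couple_lag_ts", 0.0),
                couple_lag_sf=lag_sf + shifts.get("couple_lag_sf", 0.0),
                seed=int(seed),
            )
            for k in range(n_gait):
                trials.append(generate_gait_trial(gm, condition, k, sid))
            for k in range(n_hop):
                trials.append(generate_hop_trial(hm, condition, k, sid))
    return trials
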
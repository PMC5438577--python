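"""Trial data model, plain-text readers/writers and run configuration.

A *trial* is one recording of a subject performing a task (level walking
or a one-leg hop) under one condition (knee sleeve worn or not).  Each
trial carries sagittal segment angles for the thigh, shank and foot (in
degrees, angle to the vertical, positive counter-clockwise when the
direction of progression is +x), optional 3-D marker tracks (metres;
x = progression, y = mediolateral, z = vertical up, right handed) and
the vertical ground-reaction force (newtons) used for contact-event
detection.

Canonical on-disk format is a CSV with one sample per row: a ``time``
column, one column per segment angle (``thigh``/``shank``/``foot``),
``grf_vertical``, and marker triplets as ``<name>_x, <name>_y, <name>_z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, SamplingError

SEGMENTS = ("thigh", "shank", "foot")
TASKS = ("gait", "hop")
CONDITIONS = ("sleeve", "none")

#: relative tolerance on the uniform time step (seconds)
_DT_ATOL = 1e-9


@dataclass
class Trial:
    """One recording: channels, sampling rate and metadata."""

    subject_id: str
    task: str
    condition: str
    trial_index: int
    fs: float
    time: np.ndarray
    angles: dict[str, np.ndarray] = field(default_factory=dict)
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    grf_vertical: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angles = {k: np.asarray(v, dtype=float) for k, v in self.angles.items()}
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        if self.grf_vertical is not None:
            self.grf_vertical = np.asarray(self.grf_vertical, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.time.size

    def validate(self) -> "Trial":
        """Check the trial invariants; return self for chaining."""
        if self.task not in TASKS:
            raise FormatError(f"unknown task {self.task!r}")
        if self.condition not in CONDITIONS:
            raise FormatError(f"unknown condition {self.condition!r}")
        if self.fs <= 0:
            raise SamplingError(f"sampling rate must be positive, got {self.fs}")
        n = self.n_samples
        if n < 2:
            raise FormatError("trial must contain at least 2 samples")
        if self.grf_vertical is None:
            raise FormatError("missing required channel 'grf_vertical'")
        for name, arr in self.angles.items():
            if name not in SEGMENTS:
                raise FormatError(f"unknown segment {name!r}")
            if arr.shape != (n,):
                raise FormatError(f"angle channel {name!r} length mismatch")
        for name, arr in self.markers.items():
            if arr.shape != (n, 3):
                raise FormatError(f"marker {name!r} must be (n, 3)")
        if self.grf_vertical.shape != (n,):
            raise FormatError("grf_vertical length mismatch")
        dt = np.diff(self.time)
        if np.any(np.abs(dt - 1.0 / self.fs) > _DT_ATOL):
            raise SamplingError(
                f"time vector is not uniform at fs={self.fs} Hz within {_DT_ATOL} s"
            )
        if not self.angles and not self.markers:
            raise FormatError("trial needs angle channels or marker tracks")
        return self


@dataclass
class RunConfig:
    """All tunable constants of the pipeline with their defaults.

    ``cutoff_hz``/``filter_order`` parameterise the zero-lag Butterworth
    smoothing (6 Hz, order 4 per pass, forward-backward).  ``grf_threshold_n``
    operationalises "zero ground-reaction force" for event detection.
    ``n_points`` is the length of the normalised 0-100% time base.
    """

    cutoff_hz: float = 6.0
    filter_order: int = 4
    grf_threshold_n: float = 10.0
    n_points: int = 101
    normalization_scope: str = "whole_cycle"  # or "per_phase"
    sd_mode: str = "across_trials"  # or "within_curve"
    rms_mode: str = "ensemble"  # or "per_trial"
    velocity_normalization: str = "min_max"  # or "max_abs"
    alpha: float = 0.05
    holm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ConfigurationError("cutoff_hz must be positive")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        if self.grf_threshold_n <= 0:
            raise ConfigurationError("grf_threshold_n must be positive")
        if self.n_points < 3:
            raise ConfigurationError("n_points must be >= 3")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.normalization_scope not in ("whole_cycle", "per_phase"):
            raise ConfigurationError(
                f"unknown normalization_scope {self.normalization_scope!r}"
            )
        if self.sd_mode not in ("across_trials", "within_curve"):
            raise ConfigurationError(f"unknown sd_mode {self.sd_mode!r}")
        if self.rms_mode not in ("ensemble", "per_trial"):
            raise ConfigurationError(f"unknown rms_mode {self.rms_mode!r}")
        if self.velocity_normalization not in ("min_max", "max_abs"):
            raise ConfigurationError(
                f"unknown velocity_normalization {self.velocity_normalization!r}"
            )

    def check_against_fs(self, fs: float) -> None:
        if self.cutoff_hz >= fs / 2.0:
            raise ConfigurationError(
                f"cutoff_hz={self.cutoff_hz} must be below the Nyquist rate {fs / 2}"
            )

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


@dataclass
class ComparisonRow:
    """One paired-condition test result, the row shape of a results table."""

    parameter: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    test: str  # "paired_t" | "wilcoxon"
    statistic: float
    p: float
    n: int
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise FormatError(f"p must lie in [0, 1], got {self.p}")
        if self.n < 2:
            raise FormatError("a comparison needs at least 2 pairs")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read a YAML/JSON config file; ``None`` or an empty file gives defaults.

    Unknown keys are rejected so typos never silently fall back to defaults.
    """
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data)}")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:  # wrong value type
        raise ConfigurationError(str(exc)) from exc


def _infer_fs(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0 or np.any(dt <= 0):
        raise SamplingError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > _DT_ATOL):
        raise SamplingError("time column is not uniformly sampled")
    return 1.0 / med


def load_trial_csv(path: str | Path, meta: Mapping[str, object]) -> Trial:
    """Load a trial CSV and attach metadata.

    ``meta`` must provide ``subject_id``, ``task``, ``condition`` and
    ``trial_index``; an optional ``fs`` is cross-checked against the rate
    inferred from the time column.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise FormatError(f"{path.name}: missing required column 'time'")
    if "grf_vertical" not in df.columns:
        raise FormatError(f"{path.name}: missing required column 'grf_vertical'")
    time = df["time"].to_numpy(dtype=float)
    fs = _infer_fs(time)
    meta_fs = meta.get("fs")
    if meta_fs is not None and not math.isclose(fs, float(meta_fs), rel_tol=1e-6):
        raise SamplingError(
            f"{path.name}: inferred fs {fs:.6g} Hz disagrees with metadata fs {meta_fs}"
        )
    angles = {s: df[s].to_numpy(dtype=float) for s in SEGMENTS if s in df.columns}
    markers: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col.endswith("_x"):
            name = col[:-2]
            cols = [f"{name}_x", f"{name}_y", f"{name}_z"]
            if all(c in df.columns for c in cols):
                markers[name] = df[cols].to_numpy(dtype=float)
    trial = Trial(
        subject_id=str(meta["subject_id"]),
        task=str(meta["task"]),
        condition=str(meta["condition"]),
        trial_index=int(meta["trial_index"]),
        fs=fs,
        time=time,
        angles=angles,
        markers=markers,
        grf_vertical=df["grf_vertical"].to_numpy(dtype=float),
    )
    return trial.validate()


def write_trial_csv(trial: Trial, path: str | Path) -> Path:
    """Write a trial to CSV at full float precision (lossless round-trip)."""
    path = Path(path)
    data: dict[str, np.ndarray] = {"time": trial.time}
    for seg in SEGMENTS:
        if seg in trial.angles:
            data[seg] = trial.angles[seg]
    for name, xyz in trial.markers.items():
        for j, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = xyz[:, j]
    data["grf_vertical"] = trial.grf_vertical
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def format_p(p: float) -> str:
    """Render a p-value at 3 decimals, small values as ``<0.001``."""
    if p < 0.0005:
        return "<0.001"
    return f"{p:.3f}"


def parse_p(text: str) -> float:
    text = text.strip()
    if text.startswith("<"):
        return float(text[1:])
    return float(text)


_RESULT_COLUMNS = [
    "parameter",
    "mean_a",
    "sd_a",
    "mean_b",
    "sd_b",
    "test",
    "statistic",
    "p",
    "n",
    "note",
]


def write_results_table(rows: list[ComparisonRow], path: str | Path) -> Path:
    """Write comparison rows as CSV: means/SDs at 1 decimal, p at 3 decimals."""
    if not rows:
        raise FormatError("results table needs at least one row")
    path = Path(path)
    records = []
    for r in rows:
        records.append(
            {
                "parameter": r.parameter,
                "mean_a": f"{r.mean_a:.1f}",
                "sd_a": f"{r.sd_a:.1f}",
                "mean_b": f"{r.mean_b:.1f}",
                "sd_b": f"{r.sd_b:.1f}",
                "test": r.test,
                "statistic": f"{r.statistic:.3f}",
                "p": format_p(r.p),
                "n": r.n,
                "note": r.note,
            }
        )
    pd.DataFrame.from_records(records, columns=_RESULT_COLUMNS).to_csv(
        path, index=False
    )
    return path


def read_results_table(path: str | Path) -> list[ComparisonRow]:
    """Parse a written results table back to rows (at printed precision)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    rows = []
    for _, rec in df.iterrows():
        rows.append(
            ComparisonRow(
                parameter=rec["parameter"],
                mean_a=float(rec["mean_a"]),
                sd_a=float(rec["sd_a"]),
                mean_b=float(rec["mean_b"]),
                sd_b=float(rec["sd_b"]),
                test=rec["test"],
                statistic=float(rec["statistic"]),
                p=parse_p(rec["p"]),
                n=int(rec["n"]),
                note=rec["note"],
            )
        )
    return rows
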
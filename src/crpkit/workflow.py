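"""Study-level orchestration: simulate a cohort to disk, analyse a
directory of trials, and compare conditions.

These functions back both the ``crpkit`` command-line interface and the
numbered drivers in ``analysis/``; everything they compute lives in the
module layer (pipeline, crp_core, kinematics, group_stats).
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path

import pandas as pd

from . import synthetic_data
from .group_stats import PairedSample, build_comparison_table
from .pipeline import TrialResult, analyze_all_cycles, analyze_trial, summarize_cell
from .trial_io import (
    ComparisonRow,
    RunConfig,
    Trial,
    load_trial_csv,
    write_trial_csv,
)

_TRIAL_NAME = re.compile(
    r"(?P<subject>[A-Za-z0-9]+)_(?P<task>gait|hop)_(?P<condition>sleeve|none)"
    r"_(?P<index>\d+)\.csv$"
)


def trial_filename(trial: Trial) -> str:
    return (
        f"{trial.subject_id}_{trial.task}_{trial.condition}_{trial.trial_index}.csv"
    )


def write_cohort(trials: list[Trial], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [write_trial_csv(t, outdir / trial_filename(t)) for t in trials]


def load_trials_dir(trials_dir: str | Path) -> list[Trial]:
    """Load every trial CSV in a directory, metadata parsed from the
    ``<subject>_<task>_<condition>_<index>.csv`` filename."""
    trials = []
    for path in sorted(Path(trials_dir).glob("*.csv")):
        m = _TRIAL_NAME.match(path.name)
        if not m:
            continue
        trials.append(
            load_trial_csv(
                path,
                {
                    "subject_id": m["subject"],
                    "task": m["task"],
                    "condition": m["condition"],
                    "trial_index": int(m["index"]),
                },
            )
        )
    return trials


def simulate_cohort(
    outdir: str | Path,
    n_subjects: int = 11,
    effect: dict[str, float] | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
    **kwargs,
) -> list[Path]:
    """Generate a full synthetic study and write it as trial CSVs."""
    trials = synthetic_data.generate_cohort(
        n_subjects=n_subjects, effect=effect, seed=seed, **kwargs
    )
    return write_cohort(trials, outdir)


def analyze_study(
    trials: list[Trial], config: RunConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Run the per-trial pipeline on a whole study and tabulate.

    Returns three tidy tables: ``crp`` (per-phase RMS/SD of each couple,
    one row per subject x task x condition x couple x phase),
    ``landmarks`` (per-trial segment-angle landmarks averaged to the
    subject level) and ``spatiotemporal`` (gait trials only, averaged to
    the subject level).
    """
    config = config or RunConfig()
    cells: dict[tuple[str, str, str], list[TrialResult]] = defaultdict(list)
    lm_rows, st_rows = [], []
    for trial in trials:
        cycle_results = analyze_all_cycles(trial, config)
        cells[(trial.subject_id, trial.task, trial.condition)].extend(cycle_results)
        for res in cycle_results:
            for seg, lm in res.landmarks.items():
                lm_rows.append(
                    {
                        "subject": trial.subject_id,
                        "task": trial.task,
                        "condition": trial.condition,
                        "trial": trial.trial_index,
                        "segment": seg,
                        "initial": lm.initial,
                        "min": lm.min,
                        "max": lm.max,
                        "first_peak": lm.first_peak,
                        "second_peak": lm.second_peak,
                    }
                )
        if cycle_results[0].spatiotemporal is not None:
            st = cycle_results[0].spatiotemporal
            st_rows.append(
                {
                    "subject": trial.subject_id,
                    "condition": trial.condition,
                    "trial": trial.trial_index,
                    "velocity": st.velocity,
                    "cadence": st.cadence,
                    "step_width": st.step_width,
                    "stride_length": st.stride_length,
                    "stance_pct": st.stance_pct,
                    "swing_pct": st.swing_pct,
                }
            )
    crp_rows = []
    for (subject, task, condition), results in cells.items():
        for s in summarize_cell(results, config):
            crp_rows.append(
                {
                    "subject": subject,
                    "task": task,
                    "condition": condition,
                    "couple": s.couple,
                    "phase": s.phase,
                    "rms": s.rms,
                    "sd": s.sd,
                    "n_trials": s.n_trials,
                }
            )
    lm = pd.DataFrame(lm_rows)
    if not lm.empty:
        lm = (
            lm.groupby(["subject", "task", "condition", "segment"], as_index=False)
            .mean(numeric_only=True)
            .drop(columns=["trial"])
        )
    st = pd.DataFrame(st_rows)
    if not st.empty:
        st = (
            st.groupby(["subject", "condition"], as_index=False)
            .mean(numeric_only=True)
            .drop(columns=["trial"])
        )
    return {"crp": pd.DataFrame(crp_rows), "landmarks": lm, "spatiotemporal": st}


def _paired_from_wide(
    df: pd.DataFrame, value_col: str, key_cols: list[str]
) -> list[PairedSample]:
    samples = []
    for keys, grp in df.groupby(key_cols, sort=False):
        wide = grp.pivot(index="subject", columns="condition", values=value_col)
        if not {"none", "sleeve"} <= set(wide.columns):
            continue
        wide = wide.dropna()
        name = "_".join(str(k) for k in (keys if isinstance(keys, tuple) else (keys,)))
        samples.append(
            PairedSample(
                parameter=f"{name}_{value_col}",
                values_a=wide["none"].to_numpy(),
                values_b=wide["sleeve"].to_numpy(),
            )
        )
    return samples


def compare_study(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05, holm: bool = False
) -> dict[str, list[ComparisonRow]]:
    """Paired no-sleeve (a) vs sleeve (b) comparisons for every CRP
    RMS/SD cell, every landmark and every spatiotemporal parameter."""
    out: dict[str, list[ComparisonRow]] = {}
    crp = tables["crp"]
    if not crp.empty:
        samples = _paired_from_wide(crp, "rms", ["task", "couple", "phase"])
        samples += _paired_from_wide(crp, "sd", ["task", "couple", "phase"])
        out["crp"] = build_comparison_table(samples, alpha=alpha, holm=holm)
    lm = tables["landmarks"]
    if not lm.empty:
        samples = []
        for col in ("initial", "min", "max", "first_peak", "second_peak"):
            sub = lm.dropna(subset=[col]) if col in lm else pd.DataFrame()
            if not sub.empty:
                samples += _paired_from_wide(sub, col, ["task", "segment"])
        if samples:
            out["landmarks"] = build_comparison_table(samples, alpha=alpha, holm=holm)
    st = tables["spatiotemporal"]
    if not st.empty:
        samples = []
        for col in (
            "velocity",
            "cadence",
            "step_width",
            "stride_length",
            "stance_pct",
            "swing_pct",
        ):
            sub = st[["subject", "condition", col]].copy()
            sub["task"] = "gait"
            samples += _paired_from_wide(sub, col, ["task"])
        out["spatiotemporal"] = build_comparison_table(samples, alpha=alpha, holm=holm)
    return out
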
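"""Generate the synthetic study: 11 subjects, sleeve vs no-sleeve,
5 walking and 3 one-leg-hop trials per condition.

The sleeve condition carries a known injected +8 deg thigh->shank phase
lag so the downstream comparison has a ground-truth effect to find.
Trial CSVs are bulky scratch data and go under scratch/trials by default.

Usage: python analysis/01_simulate.py [--out scratch/trials] [--seed 1]
"""

import argparse
from pathlib import Path

from crpkit.workflow import simulate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="scratch/trials", type=Path)
    ap.add_argument("--seed", default=1, type=int)
    ap.add_argument("--subjects", default=11, type=int)
    args = ap.parse_args()

    paths = simulate_cohort(
        args.out,
        n_subjects=args.subjects,
        effect={"couple_lag_ts": 8.0},
        seed=args.seed,
    )
    n_gait = sum("gait" in p.name for p in paths)
    n_hop = len(paths) - n_gait
    print(f"wrote {len(paths)} trials ({n_gait} gait, {n_hop} hop) to {args.out}")
    print("injected effect: +8 deg thigh->shank phase lag in the sleeve condition")


if __name__ == "__main__":
    main()
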
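"""Paired sleeve vs no-sleeve comparisons of every derived parameter.

Reads the tidy tables written by 02_crp_pipeline.py and runs the
normality-gated paired procedure (Shapiro-Wilk on differences, then
paired t or Wilcoxon signed-rank) on each CRP RMS/SD cell, each
segment-angle landmark and each spatiotemporal parameter.  Writes
comparison_*.csv under results/ and prints the parameters whose
difference reaches p < 0.05 — the injected +8 deg thigh->shank lag
should surface in the CRP_TS rows.

Usage: python analysis/03_compare_conditions.py [--results results]
"""

import argparse
from pathlib import Path

import pandas as pd

from crpkit.trial_io import write_results_table
from crpkit.workflow import compare_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results", type=Path)
    ap.add_argument("--alpha", default=0.05, type=float)
    args = ap.parse_args()

    tables = {
        name: (
            pd.read_csv(args.results / f"{name}.csv")
            if (args.results / f"{name}.csv").exists()
            else pd.DataFrame()
        )
        for name in ("crp", "landmarks", "spatiotemporal")
    }
    comparisons = compare_study(tables, alpha=args.alpha)
    for name, rows in comparisons.items():
        path = write_results_table(rows, args.results / f"comparison_{name}.csv")
        sig = [r for r in rows if r.p < args.alpha]
        print(f"{name}: {len(rows)} parameters compared -> {path}")
        for r in sig:
            print(
                f"  {r.parameter}: {r.mean_a:.1f}±{r.sd_a:.1f} vs "
                f"{r.mean_b:.1f}±{r.sd_b:.1f} ({r.test}, p={r.p:.3f})"
            )


if __name__ == "__main__":
    main()
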
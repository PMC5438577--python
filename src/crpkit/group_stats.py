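"""Paired condition comparisons with a normality gate.

For each parameter the two conditions are compared on paired,
per-subject values: a Shapiro-Wilk test on the paired differences
decides between a paired t-test (differences consistent with
normality) and a Wilcoxon signed-rank test (otherwise).  Two-sided
p-values; no multiplicity adjustment by default (a Holm option is
available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CrpkitError, FormatError
from .trial_io import ComparisonRow


@dataclass
class PairedSample:
    """Per-subject values of one parameter under two conditions,
    paired by position."""

    parameter: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape:
            raise FormatError(f"{self.parameter}: paired arrays differ in length")
        if self.values_a.ndim != 1 or self.values_a.size < 3:
            raise FormatError(f"{self.parameter}: need >= 3 pairs")
        if not (
            np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))
        ):
            raise FormatError(f"{self.parameter}: missing/non-finite values")


def compare_paired(sample: PairedSample, alpha: float = 0.05) -> ComparisonRow:
    """Normality-gated paired test on one parameter.

    Shapiro-Wilk is run on the paired differences (the quantity whose
    distribution the paired t-test assumes normal).  If its p >= alpha
    the paired t-test is used; otherwise the Wilcoxon signed-rank test
    (zero differences dropped, average ranks for ties, exact null
    distribution at small n without ties, normal approximation
    otherwise).  All-zero differences give a flagged degenerate result
    with p = 1.
    """
    a, b = sample.values_a, sample.values_b
    d = a - b
    n = int(d.size)
    mean_a, sd_a = float(np.mean(a)), float(np.std(a, ddof=1))
    mean_b, sd_b = float(np.mean(b)), float(np.std(b, ddof=1))
    if np.ptp(d) < 1e-12 * max(1.0, float(np.max(np.abs(d)))):
        return ComparisonRow(
            parameter=sample.parameter,
            mean_a=mean_a,
            sd_a=sd_a,
            mean_b=mean_b,
            sd_b=sd_b,
            test="paired_t",
            statistic=0.0,
            p=1.0,
            n=n,
            note="degenerate: constant paired differences",
        )
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= alpha:
        res = stats.ttest_rel(a, b)
        test, statistic, p = "paired_t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=False, method="auto"
        )
        test, statistic, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    return ComparisonRow(
        parameter=sample.parameter,
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        test=test,
        statistic=statistic,
        p=p,
        n=n,
    )


def build_comparison_table(
    samples: list[PairedSample], alpha: float = 0.05, holm: bool = False
) -> list[ComparisonRow]:
    """One comparison row per parameter, order preserved.

    By default p-values are reported unadjusted against alpha; with
    ``holm=True`` they are Holm step-down adjusted.
    """
    if not samples:
        raise CrpkitError("no paired samples supplied")
    names = [s.parameter for s in samples]
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise CrpkitError(f"duplicate parameter names: {dupes}")
    rows = [compare_paired(s, alpha) for s in samples]
    if holm:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p for r in rows], alpha=alpha, method="holm")[1]
        for r, p_adj in zip(rows, adj):
            r.p = float(p_adj)
            r.note = (r.note + "; " if r.note else "") + "holm-adjusted"
    return rows
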
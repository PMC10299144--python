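"""Descriptive and inferential cohort summaries.

Continuous variables are reported as mean +/- sample SD; flags as counts
with percentages (both one-decimal and nearest-integer roundings, half
away from zero, matching the mixed precision of clinical reporting).
Paired continuous change uses the paired t-test; paired flag change uses
the exact McNemar test on discordant pairs; association uses Pearson's r.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar

from .cohort import CONTINUOUS_COLUMNS, FLAG_COLUMNS, PAIRED_CONTINUOUS, PAIRED_FLAGS


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (zero variance input)."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (68.5 -> 69, -68.5 -> -69)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class FlagSummary:
    count: int
    n: int
    percentage: float          # raw 100*count/n
    percentage_1dp: float
    percentage_int: int


@dataclass
class ContinuousSummary:
    mean: float
    sd: float
    n: int


@dataclass
class CohortSummary:
    continuous: dict[str, ContinuousSummary] = field(default_factory=dict)
    flags: dict[str, FlagSummary] = field(default_factory=dict)
    paired_tests: dict[str, dict] = field(default_factory=dict)
    correlations: dict[str, dict] = field(default_factory=dict)


def summarize_flag(series: pd.Series) -> FlagSummary:
    vals = series.dropna()
    n = len(vals)
    count = int(vals.sum())
    pct = 100.0 * count / n
    return FlagSummary(
        count=count,
        n=n,
        percentage=pct,
        percentage_1dp=round_half_away(pct, 1),
        percentage_int=int(round_half_away(pct, 0)),
    )


def paired_t_test(pre, post) -> tuple[float, float, float]:
    """One-sample t on the paired differences ``post - pre``.

    Returns ``(t, p, mean_diff)`` with a two-sided p from Student's t on
    n-1 degrees of freedom.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("paired t-test needs two equal-length vectors, n >= 2")
    diff = post - pre
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        raise DegenerateTestError(
            f"paired differences are constant ({diff[0]:g}): t undefined"
        )
    res = sps.ttest_1samp(diff, 0.0)
    return float(res.statistic), float(res.pvalue), mean_diff


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p (t-distribution)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("pearson needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_flags_test(pre_flags, post_flags) -> tuple[float, float]:
    """Exact McNemar test for a change in a paired binary flag.

    Uses the discordant pairs only (binomial, two-sided).  With no
    discordant pairs the change is untestable: returns ``(0, 1.0)``
    with a warning rather than an error.
    """
    pre = np.asarray(pre_flags).astype(int)
    post = np.asarray(post_flags).astype(int)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired flags must be equal-length binary vectors")
    b = int(((pre == 1) & (post == 0)).sum())  # 1 -> 0
    c = int(((pre == 0) & (post == 1)).sum())  # 0 -> 1
    if b + c == 0:
        warnings.warn("no discordant pairs: McNemar test degenerate, p = 1")
        return 0.0, 1.0
    table = [[int(((pre == 1) & (post == 1)).sum()), b],
             [c, int(((pre == 0) & (post == 0)).sum())]]
    res = mcnemar(table, exact=True)
    return float(res.statistic), float(res.pvalue)


def summarize_cohort(table: pd.DataFrame) -> CohortSummary:
    """Full descriptive + inferential summary of a cohort table.

    Summarizes every known continuous and flag column present, runs the
    paired t-test on each (baseline, 12-month) continuous pair, the exact
    McNemar test on each flag pair, and the baseline-BCVA vs final-BCVA
    Pearson correlation.  Degenerate tests are recorded, not raised.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    out = CohortSummary()
    for col in CONTINUOUS_COLUMNS:
        if col in table:
            vals = table[col].dropna()
            if len(vals):
                out.continuous[col] = ContinuousSummary(
                    mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=len(vals)
                )
    for col in FLAG_COLUMNS:
        if col in table:
            vals = table[col].dropna()
            if len(vals):
                out.flags[col] = summarize_flag(vals)
    for pre_col, post_col in PAIRED_CONTINUOUS:
        if pre_col in table and post_col in table:
            paired = table[[pre_col, post_col]].dropna()
            if len(paired) < 2:
                continue
            try:
                t, p, md = paired_t_test(paired[pre_col], paired[post_col])
                out.paired_tests[pre_col] = {
                    "t": t, "p": p, "mean_diff": md, "n": len(paired)
                }
            except DegenerateTestError as exc:
                out.paired_tests[pre_col] = {"degenerate": str(exc), "n": len(paired)}
    for pre_col, post_col in PAIRED_FLAGS:
        if pre_col in table and post_col in table:
            paired = table[[pre_col, post_col]].dropna()
            if not len(paired):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = paired_flags_test(paired[pre_col], paired[post_col])
            out.paired_tests[f"{pre_col}_flag"] = {
                "statistic": stat, "p": p, "n": len(paired)
            }
    if "bcva_baseline" in table and "bcva_final" in table:
        paired = table[["bcva_baseline", "bcva_final"]].dropna()
        if len(paired) >= 3:
            try:
                r, p = pearson(paired["bcva_baseline"], paired["bcva_final"])
                out.correlations["bcva_baseline_vs_final"] = {
                    "r": r, "p": p, "n": len(paired)
                }
            except DegenerateTestError:
                pass
    return out


def summary_to_dict(summary: CohortSummary) -> dict:
    """JSON-serializable view of a :class:`CohortSummary`."""
    return {
        "continuous": {k: vars(v) for k, v in summary.continuous.items()},
        "flags": {k: vars(v) for k, v in summary.flags.items()},
        "paired_tests": summary.paired_tests,
        "correlations": summary.correlations,
    }


_REPORT_ROWS = [
    ("BCVA (ETDRS letters)", "bcva_baseline", "bcva_final"),
    ("CMT (µm)", "cmt_baseline", "cmt_final"),
    ("SCP VPD (fraction of image area)", "vpd_scp", "vpd_scp_m12"),
    ("SCP LAC", "lac_scp", "lac_scp_m12"),
    ("DCP VPD (fraction of image area)", "vpd_dcp", "vpd_dcp_m12"),
    ("DCP LAC", "lac_dcp", "lac_dcp_m12"),
]


def summary_report_markdown(summary: CohortSummary) -> str:
    """Markdown report mirroring the baseline vs 12-month table layout."""
    lines = [
        "| Variable | Baseline | 12-month follow-up | p |",
        "|---|---|---|---|",
    ]
    for label, pre_col, post_col in _REPORT_ROWS:
        pre = summary.continuous.get(pre_col)
        post = summary.continuous.get(post_col)
        if pre is None:
            continue
        test = summary.paired_tests.get(pre_col, {})
        p = test.get("p")
        p_str = f"{p:.4g}" if p is not None else "—"
        post_str = f"{post.mean:.2f} ± {post.sd:.2f}" if post else "—"
        lines.append(
            f"| {label} | {pre.mean:.2f} ± {pre.sd:.2f} | {post_str} | {p_str} |"
        )
    if summary.flags:
        lines += ["", "| Flag | count/n | % |", "|---|---|---|"]
        for name, f in summary.flags.items():
            lines.append(f"| {name} | {f.count}/{f.n} | {f.percentage_1dp} |")
    return "\n".join(lines) + "\n"
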
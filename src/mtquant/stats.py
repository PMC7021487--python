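"""Group statistics in figure-legend style.

Summaries are mean ± SEM with t-based 95% confidence intervals; pairwise
comparisons use the classic pooled-variance Student's t-test or a one-way
fixed-effects ANOVA followed by Sidak- or Tukey-corrected post-hoc pairs.
Sidak is applied to the *requested* subset of m pairs (legends typically
compare selected pairs, not all): adjusted_p = 1 − (1 − raw_p)^m with raw
p-values from pairwise t statistics using the pooled within-group mean
square.  Western-blot quantification normalizes a phospho/total ratio to
the control lane's ratio, cancelling loading differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "BlotRatio",
    "group_summary",
    "student_t_test",
    "anova_posthoc",
    "sidak_adjust",
    "blot_ratio",
]


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float
    ci95_low: float
    ci95_high: float


@dataclass
class ComparisonResult:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float
    method: str            # student_t | anova_sidak | anova_tukey
    statistic: float
    degenerate: bool = False


@dataclass
class BlotRatio:
    phospho: float
    total: float
    ratio: float
    normalized_ratio: float   # fold of the control lane's ratio


def group_summary(values: Sequence[float], group: str = "",
                  confidence: float = 0.95) -> GroupSummary:
    """Mean ± SEM and a t-distribution confidence interval (n−1 df)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("group_summary needs n >= 2")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(n))
    tq = float(sps.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    return GroupSummary(group=group, n=n, mean=mean, sem=sem,
                        ci95_low=mean - tq * sem, ci95_high=mean + tq * sem)


def student_t_test(a: Sequence[float], b: Sequence[float],
                   two_tailed: bool = True,
                   welch: bool = False,
                   labels: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Classic pooled-variance Student's t-test (Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not welch and a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return ComparisonResult(pair=labels, raw_p=1.0, adjusted_p=1.0,
                                    method="student_t", statistic=0.0)
        return ComparisonResult(pair=labels, raw_p=0.0, adjusted_p=0.0,
                                method="student_t", statistic=float("inf"),
                                degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=not welch,
                        alternative="two-sided" if two_tailed else "greater")
    return ComparisonResult(pair=labels, raw_p=float(res.pvalue),
                            adjusted_p=float(res.pvalue),
                            method="student_t", statistic=float(res.statistic))


def sidak_adjust(raw_p: float, m: int) -> float:
    """Sidak family-wise adjustment for m comparisons: 1 − (1 − p)^m."""
    if not (0.0 <= raw_p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    # the max guards the adjusted >= raw invariant against float rounding
    return float(max(raw_p, 1.0 - (1.0 - raw_p) ** m))


def anova_posthoc(
    groups: Mapping[str, Sequence[float]],
    correction: str = "sidak",
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[tuple[float, float], list[ComparisonResult]]:
    """One-way fixed-effects ANOVA with Sidak or Tukey post-hoc pairs.

    Returns ``((F, omnibus_p), comparisons)``.  ``pairs`` selects which
    pairwise comparisons are made (default: all); for Sidak the correction
    exponent m is the number of requested pairs, and raw p-values come from
    pairwise t statistics using the pooled within-group mean square with
    N − k degrees of freedom.  Tukey uses the studentized-range
    distribution over all groups.
    """
    labels = list(groups)
    data = {g: np.asarray(groups[g], dtype=float) for g in labels}
    if len(labels) < 3:
        raise ValueError("anova_posthoc needs >= 3 groups")
    for g, x in data.items():
        if x.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
    if pairs is None:
        pairs = list(combinations(labels, 2))
    m = len(pairs)

    N = sum(x.size for x in data.values())
    k = len(labels)
    grand = np.concatenate(list(data.values())).mean()
    ss_within = sum(float(((x - x.mean()) ** 2).sum()) for x in data.values())
    ss_between = sum(x.size * (x.mean() - grand) ** 2 for x in data.values())
    df_w, df_b = N - k, k - 1
    mse = ss_within / df_w
    if mse == 0.0:
        F = 0.0 if ss_between == 0.0 else float("inf")
        omnibus_p = 1.0 if ss_between == 0.0 else 0.0
    else:
        F = (ss_between / df_b) / mse
        omnibus_p = float(sps.f.sf(F, df_b, df_w))

    comparisons: list[ComparisonResult] = []
    if correction == "sidak":
        for ga, gb in pairs:
            xa, xb = data[ga], data[gb]
            if mse == 0.0:
                equal = xa.mean() == xb.mean()
                comparisons.append(ComparisonResult(
                    pair=(ga, gb), raw_p=1.0 if equal else 0.0,
                    adjusted_p=1.0 if equal else 0.0,
                    method="anova_sidak",
                    statistic=0.0 if equal else float("inf"),
                    degenerate=not equal))
                continue
            t = (xa.mean() - xb.mean()) / np.sqrt(
                mse * (1.0 / xa.size + 1.0 / xb.size))
            raw = float(2.0 * sps.t.sf(abs(t), df=df_w))
            comparisons.append(ComparisonResult(
                pair=(ga, gb), raw_p=raw, adjusted_p=sidak_adjust(raw, m),
                method="anova_sidak", statistic=float(t)))
    elif correction == "tukey":
        res = sps.tukey_hsd(*(data[g] for g in labels))
        idx = {g: i for i, g in enumerate(labels)}
        for ga, gb in pairs:
            i, j = idx[ga], idx[gb]
            comparisons.append(ComparisonResult(
                pair=(ga, gb), raw_p=float(res.pvalue[i, j]),
                adjusted_p=float(res.pvalue[i, j]),
                method="anova_tukey", statistic=float(res.statistic[i, j])))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return (float(F), float(omnibus_p)), comparisons


def blot_ratio(phospho: float, total: float,
               control_phospho: float, control_total: float) -> BlotRatio:
    """Phospho/total band ratio normalized to the control lane's ratio."""
    for name, v in (("phospho", phospho), ("total", total),
                    ("control_phospho", control_phospho),
                    ("control_total", control_total)):
        if v <= 0:
            raise ValueError(f"{name} signal must be > 0")
    ratio = phospho / total
    return BlotRatio(phospho=phospho, total=total, ratio=ratio,
                     normalized_ratio=ratio / (control_phospho / control_total))
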
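"""Group comparisons and figure-style numeric summaries.

Two-group comparisons use Welch's unequal-variance two-tailed t-test.
Families of comparisons against a control group are adjusted with the Šidák
closed form, p_adj = 1 - (1 - p)^m.  Distribution summaries use linear
interpolation quantiles (numpy's default) so the numbers are reproducible
across languages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    statistic: float
    raw_p: float
    adjusted_p: float
    adjustment: str
    n_a: int
    n_b: int
    test: str = "welch_t"

    def __post_init__(self) -> None:
        if not (np.isnan(self.raw_p) or 0.0 <= self.raw_p <= 1.0):
            raise ValueError("raw_p must be in [0, 1]")
        if self.adjusted_p < self.raw_p - 1e-12:
            raise ValueError("adjusted_p must be >= raw_p")


def sidak_adjust(p: float, m: int) -> float:
    """Šidák family-wise adjustment for one of m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    return float(1.0 - (1.0 - p) ** m)


def two_group_test(values_a, values_b, name_a: str = "a", name_b: str = "b",
                   adjustment_m: int = 1) -> ComparisonResult:
    """Welch two-tailed t-test between two groups.

    Degenerate convention: when both groups have zero variance, p is 1 for
    equal means and 0 otherwise (a deterministic separation needs no test).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        equal = a.mean() == b.mean()
        stat, p = 0.0 if equal else np.inf, 1.0 if equal else 0.0
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    adj = "sidak" if adjustment_m > 1 else "none"
    return ComparisonResult(
        group_a=name_a, group_b=name_b, statistic=float(stat),
        raw_p=float(p), adjusted_p=sidak_adjust(float(p), adjustment_m),
        adjustment=adj, n_a=len(a), n_b=len(b),
    )


def multi_group_vs_control(values_by_group: dict, control: str
                           ) -> list[ComparisonResult]:
    """Pairwise Welch tests of every group against the control, with Šidák
    adjustment over the m = n_groups - 1 comparisons."""
    if control not in values_by_group:
        raise ValueError(f"control group {control!r} absent from data")
    others = [g for g in values_by_group if g != control]
    if not others:
        raise ValueError("need at least one non-control group")
    m = len(others)
    return [
        two_group_test(values_by_group[g], values_by_group[control],
                       name_a=g, name_b=control, adjustment_m=m)
        for g in others
    ]


def distribution_summary(values_by_group: dict) -> pd.DataFrame:
    """Box/violin numerics per group: min, Q1, median, Q3, max, n.

    Quantiles use linear interpolation.  Degenerate groups (all values
    equal, e.g. all-zero paired distances) summarize without error.
    """
    rows = []
    for group, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if len(v) == 0:
            raise ValueError(f"group {group!r} is empty")
        q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append(dict(group=group, min=q[0], q1=q[1], median=q[2],
                         q3=q[3], max=q[4], n=len(v)))
    return pd.DataFrame(rows, columns=["group", "min", "q1", "median", "q3",
                                       "max", "n"])
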
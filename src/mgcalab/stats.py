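"""Group summaries and the chamber-comparison test battery.

Small-sample statistics used to compare Mg/Ca between the final (F0),
penultimate (F-1) and antepenultimate (F-2) chambers: mean ± SD summaries,
the two-sided F-test of variance equality, pooled/Welch t-tests (usable from
raw values or from printed mean/SD/n summaries), and Pearson correlation
with its t-based significance test. Standard deviations use the n−1
denominator throughout; all p-values are two-sided and no multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "f_test_variances",
    "t_test",
    "pearson",
    "chamber_comparison",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD (n−1) of one group of Mg/Ca values."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def var(self) -> float:
        return self.sd ** 2


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Union[float, tuple]
    p: float
    kind: Literal["t_pooled", "t_welch", "f_variance", "pearson"]

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Arithmetic mean, SD (n−1) and count; a singleton gets sd = 0."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("cannot summarize an empty group")
    if len(x) == 1:
        warnings.warn(f"group '{label}' has a single value; sd set to 0",
                      stacklevel=2)
        return GroupSummary(label=label, mean=float(x[0]), sd=0.0, n=1)
    return GroupSummary(label=label, mean=float(np.mean(x)),
                        sd=float(np.std(x, ddof=1)), n=len(x))


def _as_summary(g, label: str) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return summarize(g, label)


def f_test_variances(a, b) -> TestResult:
    """Two-sided F-test of variance equality.

    F is the larger sample variance over the smaller, with numerator/
    denominator degrees of freedom ordered accordingly; p is twice the upper
    tail (capped at 1).
    """
    ga, gb = _as_summary(a, "a"), _as_summary(b, "b")
    if ga.n < 2 or gb.n < 2:
        raise ValueError("F-test needs n >= 2 in both groups")
    if ga.var == 0 and gb.var == 0:
        raise ValueError("both groups have zero variance")
    if ga.var >= gb.var:
        num, den = ga, gb
    else:
        num, den = gb, ga
    if den.var == 0:
        raise ValueError("smaller-variance group has zero variance")
    f = num.var / den.var
    dfn, dfd = num.n - 1, den.n - 1
    p = min(1.0, 2.0 * float(sps.f.sf(f, dfn, dfd)))
    return TestResult(statistic=float(f), df=(dfn, dfd), p=p,
                      kind="f_variance")


def t_test(a, b, mode: Literal["auto", "pooled", "welch"] = "auto"
           ) -> TestResult:
    """Two-sample t-test from raw values or (mean, sd, n) summaries.

    ``mode='auto'`` pools the variances when the F-test does not reject
    equality at α = 0.05, otherwise uses the Welch statistic with
    Satterthwaite degrees of freedom. The summary-statistics path is exact:
    feeding it summaries computed from raw data reproduces the raw-data
    result.
    """
    ga, gb = _as_summary(a, "a"), _as_summary(b, "b")
    if ga.n < 2 or gb.n < 2:
        raise ValueError("t-test needs n >= 2 in both groups")
    if mode == "auto":
        mode = "pooled" if not f_test_variances(ga, gb).significant else "welch"
    if mode == "pooled":
        df = ga.n + gb.n - 2
        sp2 = ((ga.n - 1) * ga.var + (gb.n - 1) * gb.var) / df
        se = math.sqrt(sp2 * (1.0 / ga.n + 1.0 / gb.n))
        kind = "t_pooled"
    elif mode == "welch":
        va, vb = ga.var / ga.n, gb.var / gb.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (ga.n - 1) + vb ** 2 / (gb.n - 1))
        kind = "t_welch"
    else:
        raise ValueError("mode must be 'auto', 'pooled' or 'welch'")
    if se == 0:
        raise ValueError("zero standard error (both groups constant)")
    t = (ga.mean - gb.mean) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), df=float(df), p=p, kind=kind)


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided t-based p-value.

    Pairs with a missing member (NaN) are dropped; significance uses
    t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise ValueError("x and y lengths differ")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = len(xa)
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 complete pairs")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=r, df=float(df), p=p, kind="pearson")


def chamber_comparison(groups: dict[str, object],
                       mode: Literal["auto", "pooled", "welch"] = "auto"
                       ) -> tuple[list[GroupSummary], pd.DataFrame]:
    """All pairwise F- and t-tests among chamber groups.

    ``groups`` maps chamber labels (F0, F-1, F-2) to raw value sequences or
    ready-made :class:`GroupSummary` objects. Pairs where a group has n < 2
    are skipped with a warning. Returns the per-group summaries and a tidy
    table with one row per pair.
    """
    if len(groups) < 2:
        raise ValueError("need at least two chambers to compare")
    summaries = [_as_summary(g, lbl) for lbl, g in groups.items()]
    by_label = {s.label: s for s in summaries}
    labels = list(by_label)

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ga, gb = by_label[labels[i]], by_label[labels[j]]
            if ga.n < 2 or gb.n < 2:
                warnings.warn(f"skipping {ga.label} vs {gb.label}: "
                              "n < 2 in one group", stacklevel=2)
                continue
            ft = f_test_variances(ga, gb)
            tt = t_test(ga, gb, mode=mode)
            rows.append({
                "group_a": ga.label, "group_b": gb.label,
                "mean_a": ga.mean, "mean_b": gb.mean,
                "f_statistic": ft.statistic, "f_p": ft.p,
                "t_statistic": tt.statistic, "t_df": tt.df, "t_p": tt.p,
                "t_kind": tt.kind,
                "conclusion": ("significantly different"
                               if tt.p < ALPHA else "statistically similar"),
            })
    return summaries, pd.DataFrame(rows)
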
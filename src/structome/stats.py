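"""Summary statistics and significance tests for structome profiles.

Per-metric summaries (n, mean, sample SD, min, max) over cells, two-sample
t-tests — including directly from summary statistics, which is how published
species means from earlier serial-section studies are compared when the
per-cell values are not available — and one-way ANOVA.

The Welch (unequal-variance) t-test is the default: the species groups
compared here have both unequal spreads and unequal cell counts.  The
pooled (equal-variance) variant is available for sensitivity analysis.
Tests are two-sided throughout, and no multiple-testing correction is
applied by default (a Bonferroni option exists on the comparison report).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .stereology import CellProfile

Variant = Literal["welch", "pooled"]


@dataclass(frozen=True)
class MetricSummary:
    """(n, mean, sample SD, min, max) of one metric in one group.

    ``min``/``max`` are NaN when unknown (published summaries often report
    only n, mean and SD).
    """

    group_label: str
    metric: str
    n: int
    mean: float
    sd: float
    min: float = float("nan")
    max: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n >= 2 and (not math.isfinite(self.sd) or self.sd < 0):
            raise ValueError(f"sd must be finite and >= 0, got {self.sd}")
        if math.isfinite(self.min) and math.isfinite(self.max):
            if not self.min <= self.mean <= self.max:
                raise ValueError("min <= mean <= max violated")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a significance test.

    ``df`` may be fractional (Welch–Satterthwaite); ``df2`` is the
    denominator degrees of freedom for the F test and ``None`` otherwise.
    """

    statistic: float
    df: float
    p_value: float
    test_name: str
    two_sided: bool = True
    df2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if not self.df > 0:
            raise ValueError(f"df must be > 0, got {self.df}")


def summarize(values: Iterable[float], group_label: str = "",
              metric: str = "") -> MetricSummary:
    """Mean, sample SD (n-1 denominator), min and max of a set of values.

    With a single value the SD is undefined and reported as NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize needs at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("summarize requires finite values")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return MetricSummary(
        group_label=group_label, metric=metric, n=int(arr.size),
        mean=float(arr.mean()), sd=sd,
        min=float(arr.min()), max=float(arr.max()),
    )


def _two_sided_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def t_test_from_summaries(g1: MetricSummary, g2: MetricSummary,
                          variant: Variant = "welch") -> TestResult:
    """Two-sample t-test computed from group summaries alone.

    Welch: ``t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)`` with
    Welch–Satterthwaite degrees of freedom.  Pooled: the classical
    equal-variance statistic with ``n1 + n2 - 2`` degrees of freedom.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("t-test requires n >= 2 in both groups")
    if not (g1.sd > 0 or g2.sd > 0):
        raise ValueError("t-test requires sd > 0 in at least one group")
    v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
    if variant == "welch":
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
        name = "welch_t"
    elif variant == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2) / df
        se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
        name = "pooled_t"
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t = (g1.mean - g2.mean) / se
    return TestResult(statistic=t, df=df, p_value=_two_sided_p(t, df),
                      test_name=name)


def t_test_from_values(values1: Sequence[float], values2: Sequence[float],
                       variant: Variant = "welch") -> TestResult:
    """Two-sample t-test from raw values.

    Defined as :func:`t_test_from_summaries` applied to the two group
    summaries, so the two entry points agree at full precision.
    """
    return t_test_from_summaries(summarize(values1), summarize(values2),
                                 variant=variant)


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA over two or more groups.

    Returns the F statistic with (k-1, N-k) degrees of freedom.  When all
    groups are identical (zero between- and within-group variation) the
    convention F = 0, p = 1 applies.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs at least 2 values per group")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(statistic=0.0, df=df1, df2=df2, p_value=1.0,
                              test_name="one_way_anova")
        return TestResult(statistic=float("inf"), df=df1, df2=df2,
                          p_value=0.0, test_name="one_way_anova")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(statistic=float(f), df=df1, df2=df2, p_value=p,
                      test_name="one_way_anova")


@dataclass(frozen=True)
class MetricComparison:
    """One row of a two-group comparison report."""

    metric: str
    summary_a: MetricSummary
    summary_b: MetricSummary
    test: TestResult
    alpha: float
    significant: bool


def compare_profiles(table_a: Sequence[CellProfile],
                     table_b: Sequence[CellProfile] | Mapping[str, MetricSummary],
                     metrics: Sequence[str] | None = None,
                     alpha: float = 0.05,
                     variant: Variant = "welch",
                     bonferroni: bool = False,
                     label_a: str = "A", label_b: str = "B",
                     ) -> list[MetricComparison]:
    """Metric-by-metric comparison of two cell tables.

    ``table_b`` may be a list of profiles or a mapping ``metric -> summary``
    (for comparisons against published group summaries).  The significance
    flag uses ``alpha``, optionally Bonferroni-divided by the number of
    metrics; no correction is applied by default.
    """
    if metrics is None:
        if isinstance(table_b, Mapping):
            metrics = [m for m in CellProfile.METRICS if m in table_b]
        else:
            metrics = list(CellProfile.METRICS)
    known = set(CellProfile.METRICS)
    for m in metrics:
        if m not in known:
            raise ValueError(f"unknown metric {m!r}")

    if len(table_a) < 2:
        raise ValueError("comparison requires >= 2 cells per table")
    threshold = alpha / len(metrics) if bonferroni else alpha

    rows: list[MetricComparison] = []
    for m in metrics:
        sa = summarize([getattr(p, m) for p in table_a], label_a, m)
        if isinstance(table_b, Mapping):
            sb = table_b[m]
        else:
            if len(table_b) < 2:
                raise ValueError("comparison requires >= 2 cells per table")
            sb = summarize([getattr(p, m) for p in table_b], label_b, m)
        test = t_test_from_summaries(sa, sb, variant=variant)
        rows.append(MetricComparison(metric=m, summary_a=sa, summary_b=sb,
                                     test=test, alpha=threshold,
                                     significant=test.p_value < threshold))
    return rows


def format_p(p: float) -> str:
    """Human-readable p-value for text reports (JSON keeps full precision)."""
    if p < 1e-15:
        return "< 1e-15"
    return f"{p:.4g}"
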
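"""Contingency tables and group-comparison tests by AIS status.

Reproduces the descriptive surface of a case-control screening table:
per-variable counts and percentages by group, Pearson chi-square tests
(with Yates continuity correction where a 2x2 table calls for it), a
two-sample t-test for age, and simple count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variables import CATEGORICAL_VARIABLES, TABLE1_COUNTS, VARIABLES

__all__ = [
    "ContingencyTable",
    "TestResult",
    "tabulate",
    "table1_contingency",
    "chi_square",
    "two_sample_t",
    "two_sample_t_from_stats",
    "group_ratio",
    "table1_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Grouped counts of one categorical variable by AIS status.

    ``counts`` has shape (n_levels, 2) with columns (control, case).
    """

    variable: str
    levels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("counts must have shape (levels, 2)")
        if c.shape[0] != len(self.levels):
            raise ValueError("counts rows must match levels")
        if len(self.levels) < 2:
            raise ValueError("a contingency table needs at least 2 levels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_control(self) -> int:
        return int(self.counts[:, 0].sum())

    @property
    def n_case(self) -> int:
        return int(self.counts[:, 1].sum())

    def swap_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.variable, self.levels, self.counts[:, ::-1])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str  # pearson_chi2 | chi2_continuity | welch_t | student_t


def tabulate(records: pd.DataFrame, variable: str) -> ContingencyTable:
    """Cross-tabulate one categorical variable against the AIS label.

    ``counts[i, j]`` is the number of records at level *i* with ais = *j*;
    the total over the table equals the number of input records.
    """
    if variable not in VARIABLES:
        raise KeyError(f"unknown categorical variable {variable!r}")
    levels = VARIABLES[variable].levels
    if len(records):
        seen = set(records[variable].unique()) - set(levels)
        if seen:
            raise ValueError(f"{variable}: unknown level(s) {sorted(seen)}")
    counts = np.zeros((len(levels), 2), dtype=np.int64)
    for i, level in enumerate(levels):
        for j in (0, 1):
            if len(records):
                counts[i, j] = int(
                    ((records[variable] == level) & (records["ais"] == j)).sum()
                )
    return ContingencyTable(variable, levels, counts)


def table1_contingency(variable: str) -> ContingencyTable:
    """Contingency table built from the published per-level counts."""
    if variable not in TABLE1_COUNTS:
        raise KeyError(f"no published counts for {variable!r}")
    return ContingencyTable(
        variable, VARIABLES[variable].levels, np.asarray(TABLE1_COUNTS[variable])
    )


def chi_square(table: ContingencyTable, continuity: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a levels-by-status table.

    With ``continuity=True`` (2x2 tables only) applies the Yates
    correction, sum((|O-E|-0.5)^2/E).  Raises if any expected cell is zero
    (the statistic is undefined).
    """
    c = table.counts
    if continuity and c.shape != (2, 2):
        raise ValueError("continuity correction is only defined for 2x2 tables")
    expected = stats.contingency.expected_freq(c)
    if (expected == 0).any():
        raise ValueError("zero expected cell count: chi-square undefined")
    res = stats.chi2_contingency(c, correction=continuity)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.dof),
        p_value=float(res.pvalue),
        method="chi2_continuity" if continuity else "pearson_chi2",
    )


def two_sample_t(
    values_control: Sequence[float],
    values_case: Sequence[float],
    welch: bool = True,
) -> TestResult:
    """Two-sided two-sample t-test, control minus case.

    The sign convention means older cases yield a negative statistic.
    Welch's unequal-variance form is the default; ``welch=False`` pools.
    """
    a = np.asarray(values_control, dtype=float)
    b = np.asarray(values_case, dtype=float)
    for name, v in (("control", a), ("case", b)):
        if v.size < 2:
            raise ValueError(f"{name} group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        method="welch_t" if welch else "student_t",
    )


def two_sample_t_from_stats(
    mean_control: float,
    sd_control: float,
    n_control: int,
    mean_case: float,
    sd_case: float,
    n_case: int,
    welch: bool = True,
) -> TestResult:
    """t-test from published summary statistics (control minus case)."""
    res = stats.ttest_ind_from_stats(
        mean_control, sd_control, n_control, mean_case, sd_case, n_case,
        equal_var=not welch,
    )
    if welch:
        v0, v1 = sd_control**2 / n_control, sd_case**2 / n_case
        df = (v0 + v1) ** 2 / (v0**2 / (n_control - 1) + v1**2 / (n_case - 1))
    else:
        df = n_control + n_case - 2
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        method="welch_t" if welch else "student_t",
    )


def group_ratio(
    table: ContingencyTable, level_a: str, level_b: str, group: str
) -> float:
    """count(level_a, group) / count(level_b, group), group in {control, case}."""
    col = {"control": 0, "case": 1}[group]
    ia, ib = table.levels.index(level_a), table.levels.index(level_b)
    denom = table.counts[ib, col]
    if denom == 0:
        raise ZeroDivisionError(f"zero count for {level_b!r} in {group} group")
    return float(table.counts[ia, col]) / float(denom)


def table1_report(
    records: pd.DataFrame,
    continuity_vars: Iterable[str] = ("lumbar_kyphosis",),
    welch: bool = True,
) -> pd.DataFrame:
    """Per-variable counts, percentages, test statistic and p by AIS status.

    One row per categorical level plus an age row (mean ± SD, t-test).
    ``continuity_vars`` lists the 2x2 variables whose chi-square uses the
    Yates correction, matching the published table's convention.
    """
    continuity_vars = set(continuity_vars)
    rows: list[dict] = []
    ctrl_age = records.loc[records["ais"] == 0, "age"]
    case_age = records.loc[records["ais"] == 1, "age"]
    if len(ctrl_age) >= 2 and len(case_age) >= 2:
        t = two_sample_t(ctrl_age, case_age, welch=welch)
        rows.append(
            {
                "variable": "age",
                "level": "",
                "control": f"{ctrl_age.mean():.2f} ± {ctrl_age.std(ddof=1):.2f}",
                "case": f"{case_age.mean():.2f} ± {case_age.std(ddof=1):.2f}",
                "statistic": round(t.statistic, 2),
                "p_value": t.p_value,
                "method": t.method,
            }
        )
    for name in CATEGORICAL_VARIABLES:
        table = tabulate(records, name)
        try:
            test = chi_square(table, continuity=name in continuity_vars)
            stat, p, method = round(test.statistic, 2), test.p_value, test.method
        except ValueError:
            stat, p, method = np.nan, np.nan, "undefined"
        n0, n1 = max(table.n_control, 1), max(table.n_case, 1)
        for i, level in enumerate(table.levels):
            rows.append(
                {
                    "variable": name,
                    "level": level,
                    "control": f"{table.counts[i, 0]} ({100 * table.counts[i, 0] / n0:.1f})",
                    "case": f"{table.counts[i, 1]} ({100 * table.counts[i, 1] / n1:.1f})",
                    "statistic": stat if i == 0 else "",
                    "p_value": p if i == 0 else "",
                    "method": method if i == 0 else "",
                }
            )
    return pd.DataFrame(rows)
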
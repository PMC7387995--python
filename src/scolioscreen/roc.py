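"""Per-predictor discrimination: grouped rank AUC, binormal AUC, CIs.

For a categorical predictor summarized as level counts by AIS status, the
area under the ROC curve is the Mann-Whitney probability that a random
case outscores a random control, counting ties one-half:

    AUC = [#(case > control) + 0.5 * #(ties)] / (n_case * n_control)

computed in closed form from the grouped counts without enumerating
pairs.  The default score coding collapses each variable to binary
(reference/normal level -> 0, any abnormal level -> 1); an ordinal
0/1/2 coding is available through ``score_map``.  Age uses the binormal
closed form Phi(dmu / sqrt(sd1^2 + sd0^2)).  Confidence intervals follow
Hanley & McNeil's variance for an estimated AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .descriptive import ContingencyTable, tabulate
from .variables import VARIABLES

__all__ = [
    "AUCResult",
    "empirical_auc",
    "binormal_auc",
    "auc_ci",
    "figure2_report",
    "roc_coordinates",
]


@dataclass(frozen=True)
class AUCResult:
    variable: str
    auc: float
    ci_low: float
    ci_high: float
    p_value: float  # two-sided test of AUC = 0.5
    method: str  # empirical_rank | binormal

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.auc <= self.ci_high <= 1:
            raise ValueError("require 0 <= ci_low <= auc <= ci_high <= 1")


def _hanley_mcneil_se(auc: float, n_case: int, n_control: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_case - 1) * (q1 - auc * auc)
        + (n_control - 1) * (q2 - auc * auc)
    ) / (n_case * n_control)
    return float(np.sqrt(max(var, 0.0)))


def auc_ci(auc: float, n_case: int, n_control: int) -> tuple[float, float]:
    """Hanley–McNeil 95% interval, clipped to [0, 1].

    At auc exactly 0 or 1 the variance degenerates; a point interval is
    returned with a warning.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("group sizes must be positive")
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if auc in (0.0, 1.0):
        warnings.warn(
            "AUC at a boundary: variance degenerates to a point interval",
            UserWarning,
            stacklevel=2,
        )
        return (auc, auc)
    se = _hanley_mcneil_se(auc, n_case, n_control)
    return (max(auc - 1.96 * se, 0.0), min(auc + 1.96 * se, 1.0))


def _auc_from_counts(
    table: ContingencyTable, scores: np.ndarray
) -> float:
    """Closed-form ties-corrected rank AUC from grouped level counts."""
    ctrl = table.counts[:, 0].astype(float)
    case = table.counts[:, 1].astype(float)
    n0, n1 = ctrl.sum(), case.sum()
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be non-empty")
    order = np.argsort(scores, kind="stable")
    s, c0, c1 = scores[order], ctrl[order], case[order]
    # collapse equal scores
    uniq, inv = np.unique(s, return_inverse=True)
    a0 = np.bincount(inv, weights=c0, minlength=len(uniq))
    a1 = np.bincount(inv, weights=c1, minlength=len(uniq))
    below = np.concatenate(([0.0], np.cumsum(a0)[:-1]))  # controls scoring lower
    num = float(np.sum(a1 * (below + 0.5 * a0)))
    return num / (n0 * n1)


def empirical_auc(
    table: ContingencyTable, score_map: Mapping[str, float] | None = None
) -> AUCResult:
    """Rank AUC of one categorical predictor from its grouped counts.

    ``score_map`` assigns a real score to each level; by default the
    reference level scores 0 and every other level 1 (binary collapse).
    """
    if score_map is None:
        scores = np.array([0.0] + [1.0] * (len(table.levels) - 1))
    else:
        missing = [lv for lv in table.levels if lv not in score_map]
        if missing:
            raise KeyError(f"score_map missing levels {missing}")
        scores = np.array([float(score_map[lv]) for lv in table.levels])
    auc = _auc_from_counts(table, scores)
    n0, n1 = table.n_control, table.n_case
    lo, hi = auc_ci(auc, n1, n0) if 0.0 < auc < 1.0 else (auc, auc)
    se = _hanley_mcneil_se(auc, n1, n0) if 0.0 < auc < 1.0 else 0.0
    z = (auc - 0.5) / se if se > 0 else np.inf * np.sign(auc - 0.5)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return AUCResult(table.variable, float(auc), lo, hi, p, "empirical_rank")


def binormal_auc(
    mean_case: float,
    sd_case: float,
    mean_control: float,
    sd_control: float,
    n_case: int | None = None,
    n_control: int | None = None,
    variable: str = "age",
) -> AUCResult:
    """Closed-form AUC for a normally distributed score in each group."""
    if sd_case <= 0 or sd_control <= 0:
        raise ValueError("standard deviations must be positive")
    auc = float(stats.norm.cdf((mean_case - mean_control) / np.hypot(sd_case, sd_control)))
    if n_case and n_control and 0.0 < auc < 1.0:
        lo, hi = auc_ci(auc, n_case, n_control)
        se = _hanley_mcneil_se(auc, n_case, n_control)
        p = float(2 * stats.norm.sf(abs((auc - 0.5) / se))) if se > 0 else 1.0
    else:
        lo = hi = auc
        p = float("nan")
    return AUCResult(variable, auc, lo, hi, p, "binormal")


#: Variables whose discrimination the published analysis reports.
REPORTED_AUC_VARIABLES: tuple[str, ...] = (
    "gender",
    "age",
    "shoulder_height_diff",
    "scapular_tilt",
    "lumbar_concave",
    "pelvic_tilt",
    "atr_thoracic",
    "atr_thoracolumbar",
    "atr_lumbar",
)


def figure2_report(
    records: pd.DataFrame,
    variables: tuple[str, ...] = REPORTED_AUC_VARIABLES,
    ordinal: bool = False,
) -> pd.DataFrame:
    """AUC, 95% CI and p per predictor, age via the binormal form.

    ``ordinal=True`` scores three-level variables 0/1/2 instead of the
    default binary collapse.
    """
    rows = []
    for name in variables:
        if name == "age":
            ctrl = records.loc[records["ais"] == 0, "age"]
            case = records.loc[records["ais"] == 1, "age"]
            r = binormal_auc(
                case.mean(), case.std(ddof=1), ctrl.mean(), ctrl.std(ddof=1),
                n_case=len(case), n_control=len(ctrl),
            )
        else:
            table = tabulate(records, name)
            score_map = (
                {lv: float(i) for i, lv in enumerate(VARIABLES[name].levels)}
                if ordinal
                else None
            )
            r = empirical_auc(table, score_map)
        rows.append(
            {
                "variable": r.variable,
                "auc": round(r.auc, 4),
                "ci_low": round(r.ci_low, 4),
                "ci_high": round(r.ci_high, 4),
                "p_value": r.p_value,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)


def roc_coordinates(
    table: ContingencyTable, score_map: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """(FPR, TPR) at every threshold of the level scores, for curve dumps."""
    if score_map is None:
        scores = np.array([0.0] + [1.0] * (len(table.levels) - 1))
    else:
        scores = np.array([float(score_map[lv]) for lv in table.levels])
    order = np.argsort(-scores, kind="stable")
    ctrl = table.counts[order, 0].astype(float)
    case = table.counts[order, 1].astype(float)
    uniq, inv = np.unique(-scores[order], return_inverse=True)
    fp = np.bincount(inv, weights=ctrl).cumsum()
    tp = np.bincount(inv, weights=case).cumsum()
    fpr = np.concatenate(([0.0], fp / max(table.n_control, 1)))
    tpr = np.concatenate(([0.0], tp / max(table.n_case, 1)))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})
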
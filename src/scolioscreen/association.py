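"""Univariate odds ratios and multivariate logistic regression.

The univariate odds ratio for a predictor level against its reference is
computed in closed form from the 2x2 sub-table, with a Wald confidence
interval on the log scale:

    OR = (case_level * control_ref) / (control_level * case_ref)
    SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d)

A zero cell triggers the Haldane–Anscombe correction (+0.5 to all four
cells) and flags the estimate.  The multivariate model is a standard
Bernoulli GLM with logit link fitted by iteratively reweighted least
squares; adjusted odds ratios are exp(coefficient) with Wald intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .descriptive import ContingencyTable
from .model import PredictionModel, encode, encoding_terms
from .variables import VARIABLES

__all__ = [
    "EffectEstimate",
    "SeparationWarning",
    "univariate_or",
    "univariate_or_table",
    "univariate_or_continuous",
    "fit_multivariate",
    "multivariate_effects",
    "table2_report",
]

#: Normal quantile for 95% Wald intervals.
Z95 = 1.959964

#: |coefficient| beyond which a logistic fit is treated as separated.
SEPARATION_BOUND = 15.0


class SeparationWarning(UserWarning):
    """A logistic fit shows (quasi-)complete separation."""


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio (or adjusted odds ratio) for one predictor level."""

    variable: str
    level: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool = False
    corrected: bool = False  # Haldane–Anscombe +0.5 applied

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")
        if min(self.estimate, self.ci_low) <= 0:
            raise ValueError("odds ratios are strictly positive")


def univariate_or(table: ContingencyTable, level: str) -> EffectEstimate:
    """Closed-form odds ratio of *level* versus the table's first level."""
    ref = table.levels[0]
    if level == ref:
        raise ValueError("level must differ from the reference level")
    i = table.levels.index(level)
    ctrl_ref, case_ref = table.counts[0]
    ctrl_lvl, case_lvl = table.counts[i]
    cells = np.array([ctrl_ref, case_ref, ctrl_lvl, case_lvl], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells  # ctrl_ref, case_ref, ctrl_lvl, case_lvl
    or_ = (d * a) / (c * b)
    se = float(np.sqrt((1.0 / cells).sum()))
    z = np.log(or_) / se
    return EffectEstimate(
        variable=table.variable,
        level=level,
        estimate=float(or_),
        ci_low=float(np.exp(np.log(or_) - Z95 * se)),
        ci_high=float(np.exp(np.log(or_) + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        adjusted=False,
        corrected=corrected,
    )


def univariate_or_table(table: ContingencyTable) -> list[EffectEstimate]:
    """Odds ratios for every non-reference level of one variable."""
    return [univariate_or(table, level) for level in table.levels[1:]]


def univariate_or_continuous(
    records: pd.DataFrame, variable: str, outcome: str = "ais"
) -> EffectEstimate:
    """exp(slope) per unit increase from a one-predictor logistic fit."""
    x = records[variable].to_numpy(dtype=float)
    y = records[outcome].to_numpy(dtype=float)
    if np.var(x) <= 0:
        raise ValueError(f"{variable} has no variance")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is identical for all records: no model exists")
    fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit(
        maxiter=100, tol=1e-8
    )
    slope, se = float(fit.params[1]), float(fit.bse[1])
    if abs(slope) > SEPARATION_BOUND:
        raise ValueError(
            f"complete separation on {variable!r}: |slope| = {abs(slope):.1f}"
        )
    return EffectEstimate(
        variable=variable,
        level="per_unit",
        estimate=float(np.exp(slope)),
        ci_low=float(np.exp(slope - Z95 * se)),
        ci_high=float(np.exp(slope + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(slope / se))),
        adjusted=False,
    )


def fit_multivariate(
    records: pd.DataFrame, encoding: str = "dummy_expanded"
) -> PredictionModel:
    """Multivariate logistic fit of AIS on the twelve model covariates.

    Maximizes the Bernoulli log-likelihood by IRLS (at most 100
    iterations).  Rank-deficient designs raise; non-convergence and
    separation (any |coefficient| > 15) are reported through warnings and
    recorded on the returned model rather than discarding the last
    iterate.
    """
    X = encode(records, encoding)
    y = records["ais"].to_numpy(dtype=float)
    n, p = X.shape
    terms = encoding_terms(encoding)
    # A term constant over the data (e.g. a level absent from this sample)
    # has no estimable coefficient: drop it from the fit, report it as 0.
    values = X.to_numpy(dtype=float)
    estimable = np.array([np.ptp(values[:, j]) > 0 for j in range(p)])
    if not estimable.all():
        dropped = [t for t, ok in zip(terms, estimable) if not ok]
        warnings.warn(
            f"constant term(s) dropped from the fit (coefficient 0): {dropped}",
            UserWarning,
            stacklevel=2,
        )
    design = sm.add_constant(values[:, estimable], has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    if n < 20 * (p + 1):
        warnings.warn(
            f"only {n} records for {p + 1} parameters "
            "(fewer than 20 per parameter)",
            UserWarning,
            stacklevel=2,
        )
    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
        maxiter=100, tol=1e-8
    )
    converged = bool(getattr(fit, "converged", True))
    coef = np.zeros(p + 1)
    coef[np.concatenate(([True], estimable))] = np.asarray(fit.params, dtype=float)
    se = np.full(p + 1, np.nan)
    se[np.concatenate(([True], estimable))] = np.asarray(fit.bse, dtype=float)
    separated = tuple(
        t for t, b in zip(terms, coef[1:]) if abs(b) > SEPARATION_BOUND
    )
    if separated:
        warnings.warn(
            f"possible complete separation on: {', '.join(separated)}",
            SeparationWarning,
            stacklevel=2,
        )
    if not converged:
        warnings.warn(
            "IRLS did not converge in 100 iterations; returning last iterate",
            UserWarning,
            stacklevel=2,
        )
    return PredictionModel(
        intercept=float(coef[0]),
        terms=terms,
        coef=coef[1:],
        encoding=encoding,
        scheme="plain",
        provenance="fitted",
        se=se[1:],
        converged=converged,
        separation=separated,
    )


def multivariate_effects(model: PredictionModel) -> list[EffectEstimate]:
    """Adjusted odds ratios exp(b) with Wald 95% CIs, one per term."""
    if model.se is None:
        raise ValueError("model carries no standard errors")
    tiny = np.finfo(float).tiny
    out = []
    with np.errstate(over="ignore", under="ignore"):
        for term, b, se in zip(model.terms, model.coef, model.se):
            if not np.isfinite(se):  # term dropped as inestimable
                continue
            if "[" in term:
                variable, level = term[:-1].split("[")
            else:
                variable, level = term, "per_unit"
            z = b / se if se > 0 else np.inf * np.sign(b)
            out.append(
                EffectEstimate(
                    variable=variable,
                    level=level,
                    estimate=max(float(np.exp(b)), tiny),
                    ci_low=max(float(np.exp(b - Z95 * se)), tiny),
                    ci_high=max(float(np.exp(b + Z95 * se)), tiny),
                    p_value=float(2 * stats.norm.sf(abs(z))),
                    adjusted=True,
                )
            )
    return out


def table2_report(records: pd.DataFrame) -> pd.DataFrame:
    """Univariate OR and multivariate AOR per predictor level.

    Categorical variables (except school, which is descriptive only) get
    one row per non-reference level; age gets a per-year row.
    """
    from .descriptive import tabulate

    rows: list[dict] = []

    def add(e: EffectEstimate, kind: str) -> None:
        rows.append(
            {
                "variable": e.variable,
                "level": e.level,
                "model": kind,
                "estimate": round(e.estimate, 2),
                "ci_low": round(e.ci_low, 2),
                "ci_high": round(e.ci_high, 2),
                "p_value": e.p_value,
            }
        )

    for name in VARIABLES:
        if name == "school":
            continue
        for e in univariate_or_table(tabulate(records, name)):
            add(e, "univariate")
    add(univariate_or_continuous(records, "age"), "univariate")
    model = fit_multivariate(records, encoding="dummy_expanded")
    for e in multivariate_effects(model):
        add(e, "multivariate")
    return pd.DataFrame(rows)
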
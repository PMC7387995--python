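"""Coefficient-weighted logistic prediction models.

The published screening models come in four flavours: the plain
multivariate logistic fit, and variants whose coefficients are
re-weighted by each predictor's adjusted odds ratio (AOR), by its ROC
area (AUC), or by both.  The source analysis never writes down the
weighting transform, so this module implements one concrete, documented
contract:

* a weight vector assigns every model variable a positive weight: its
  AUC, the AUC-equivalent of its AOR (mean of the per-level AORs for
  three-level variables, mapped through the standard log-odds to
  common-language-effect-size conversion, see
  :func:`odds_ratio_to_auc`), or the elementwise product of the two —
  putting both weighting ingredients on the same bounded
  discrimination scale;
* weights are normalized to average 1, so uniform weights are a no-op
  and rescaling all raw weights changes nothing;
* the weighted coefficient is ``b_j * w_j / mean(w)``;
* the intercept is re-calibrated so the mean predicted probability on
  the training data equals the observed case fraction.

The four published equations themselves ship as bit-stable fixtures
(``printed_equation``): their coefficients were estimated on the original
study's 70% training split and cannot be re-derived from summary tables.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .association import multivariate_effects
from .model import PredictionModel, encode, encoding_terms
from .roc import binormal_auc, empirical_auc
from .descriptive import tabulate
from .variables import MODEL_VARIABLES

__all__ = [
    "printed_equation",
    "odds_ratio_to_auc",
    "aor_weights",
    "auc_weights",
    "scheme_weights",
    "combine_weights",
    "normalize_weights",
    "apply_weighting",
]

_SCHEME_BY_EQUATION = {
    1: "plain",
    2: "aor_weighted",
    3: "auc_weighted",
    4: "aor_auc_weighted",
}


def _load_equations() -> dict:
    text = resources.files("scolioscreen.data").joinpath("equations.json").read_text()
    return json.loads(text)


def printed_equation(which: int) -> PredictionModel:
    """One of the four published prediction equations, as a fixed model.

    Single-score encoding (0/1/2 level coding, raw years for age);
    ``provenance`` is ``printed_equation`` and the scheme tag follows the
    published footnotes (1 plain, 2 AOR-weighted, 3 AUC-weighted,
    4 AOR+AUC-weighted).
    """
    if which not in _SCHEME_BY_EQUATION:
        raise ValueError("equation number must be 1, 2, 3 or 4")
    eq = _load_equations()[str(which)]
    terms = encoding_terms("single_score")
    return PredictionModel(
        intercept=float(eq["intercept"]),
        terms=terms,
        coef=np.array([eq["coefficients"][t] for t in terms], dtype=float),
        encoding="single_score",
        scheme=eq["scheme"],
        provenance="printed_equation",
    )


def odds_ratio_to_auc(or_value: float) -> float:
    """AUC-equivalent of an odds ratio (common-language effect size).

    ln(OR) is converted to Cohen's d through the logistic-to-normal
    scale factor sqrt(3)/pi, and d to the probability that a random case
    outscores a random control, Phi(d / sqrt(2)).  Maps (0, inf) onto
    (0, 1) monotonically with OR = 1 -> 0.5, so odds-ratio weights live
    on the same bounded discrimination scale as AUC weights.
    """
    from scipy import stats

    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    d = np.log(or_value) * np.sqrt(3.0) / np.pi
    return float(stats.norm.cdf(d / np.sqrt(2.0)))


def normalize_weights(weights: Mapping[str, float]) -> dict[str, float]:
    """Validate coverage/positivity and scale weights to average 1."""
    missing = [v for v in MODEL_VARIABLES if v not in weights]
    if missing:
        raise KeyError(f"weights missing variables: {missing}")
    w = np.array([float(weights[v]) for v in MODEL_VARIABLES])
    if (w <= 0).any():
        bad = [v for v, x in zip(MODEL_VARIABLES, w) if x <= 0]
        raise ValueError(f"non-positive weight for: {bad}")
    w = w / w.mean()
    return dict(zip(MODEL_VARIABLES, w.tolist()))


def aor_weights(
    dummy_model: PredictionModel, train: pd.DataFrame | None = None
) -> dict[str, float]:
    """Per-variable AOR weights from a fitted dummy-encoded model.

    Three-level variables contribute the mean of their two level AORs;
    age and binary signs contribute exp(coefficient) directly.  A
    variable whose multivariate coefficient shows separation has no
    finite AOR; when *train* is supplied its weight falls back to the
    Haldane-corrected univariate odds ratio, which is always finite.
    """
    if dummy_model.encoding != "dummy_expanded":
        raise ValueError("AOR weights require a dummy_expanded fit")
    per_var: dict[str, list[float]] = {v: [] for v in MODEL_VARIABLES}
    for e in multivariate_effects(dummy_model):
        per_var[e.variable].append(e.estimate)
    # a variable dropped as inestimable carries no information: weight 1
    weights = {
        v: float(np.mean(vals)) if vals else 1.0 for v, vals in per_var.items()
    }
    if train is not None and dummy_model.separation:
        from .association import univariate_or_table

        for v in {t.split("[")[0] for t in dummy_model.separation} - {"age"}:
            ors = [e.estimate for e in univariate_or_table(tabulate(train, v))]
            weights[v] = float(np.mean(ors))
    return weights


def auc_weights(train: pd.DataFrame, ordinal: bool = False) -> dict[str, float]:
    """Per-variable discrimination weights: empirical AUC from the
    training split (binary collapse by default), binormal AUC for age."""
    out: dict[str, float] = {}
    for name in MODEL_VARIABLES:
        if name == "age":
            ctrl = train.loc[train["ais"] == 0, "age"]
            case = train.loc[train["ais"] == 1, "age"]
            out[name] = binormal_auc(
                case.mean(), case.std(ddof=1), ctrl.mean(), ctrl.std(ddof=1)
            ).auc
        else:
            from .variables import VARIABLES

            score_map = (
                {lv: float(i) for i, lv in enumerate(VARIABLES[name].levels)}
                if ordinal
                else None
            )
            out[name] = empirical_auc(tabulate(train, name), score_map).auc
    return out


def combine_weights(
    w1: Mapping[str, float], w2: Mapping[str, float]
) -> dict[str, float]:
    """Elementwise product of two normalized weight vectors (AOR+AUC)."""
    a, b = normalize_weights(w1), normalize_weights(w2)
    return {v: a[v] * b[v] for v in MODEL_VARIABLES}


def scheme_weights(
    scheme: str,
    w_aor: Mapping[str, float],
    w_auc: Mapping[str, float],
) -> dict[str, float]:
    """Weight vector for one weighting scheme.

    ``w_aor`` holds raw per-variable AORs (as from :func:`aor_weights`);
    they are mapped through :func:`odds_ratio_to_auc` so that both
    ingredients weight on the same bounded scale.  ``w_auc`` holds AUC
    values.  The combined scheme multiplies the two normalized vectors.
    """
    aor_scale = {v: odds_ratio_to_auc(w) for v, w in w_aor.items()}
    if scheme == "aor_weighted":
        return dict(aor_scale)
    if scheme == "auc_weighted":
        return dict(w_auc)
    if scheme == "aor_auc_weighted":
        return combine_weights(aor_scale, w_auc)
    raise ValueError(f"no weight vector for scheme {scheme!r}")


def _recalibrate_intercept(
    linear_terms: np.ndarray, target_rate: float
) -> float:
    """Intercept b0 with mean sigmoid(b0 + s) equal to target_rate."""

    def gap(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + linear_terms)))) - target_rate)

    return float(optimize.brentq(gap, -40.0, 40.0, xtol=1e-12))


def apply_weighting(
    base: PredictionModel,
    weights: Mapping[str, float],
    scheme: str,
    train: pd.DataFrame,
) -> PredictionModel:
    """Re-weight a fitted plain single-score model's coefficients.

    Coefficient j becomes ``b_j * w_j / mean(w)``; the intercept is then
    re-calibrated on *train* so the mean predicted probability equals the
    observed case fraction.  Uniform weights return the base coefficients
    unchanged (up to the recalibrated intercept, which is then the
    maximum-likelihood intercept itself).
    """
    if base.encoding != "single_score":
        raise ValueError("weighting applies to single_score models")
    wn = normalize_weights(weights)
    coef = base.coef * np.array([wn[v] for v in MODEL_VARIABLES])
    X = encode(train, "single_score").to_numpy(dtype=float)
    y = train["ais"].to_numpy(dtype=float)
    intercept = _recalibrate_intercept(X @ coef, float(y.mean()))
    return PredictionModel(
        intercept=intercept,
        terms=base.terms,
        coef=coef,
        encoding="single_score",
        scheme=scheme,
        provenance="fitted",
        se=None,
    )
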
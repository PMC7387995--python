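"""Logistic prediction model container, covariate encodings, prediction.

Two encodings of the twelve model covariates X1..X12 are supported:

``single_score``
    one number per variable — 0/1/2 for three-level laterality and ATR
    variables (normal / left / right), 0/1 for binary signs and gender,
    raw years for age.  This is the form of the published prediction
    equations (one coefficient per X).

``dummy_expanded``
    each three-level variable expands to two indicator terms against the
    ``normal`` reference, giving per-level adjusted odds ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .variables import MODEL_VARIABLES, SINGLE_SCORES, VARIABLES

__all__ = [
    "PredictionModel",
    "encode",
    "encoding_terms",
    "predict_probability",
    "classify",
]

SCHEMES = ("plain", "aor_weighted", "auc_weighted", "aor_auc_weighted")


def encoding_terms(encoding: str) -> tuple[str, ...]:
    """Design-matrix column names (excluding intercept) for an encoding."""
    if encoding == "single_score":
        return MODEL_VARIABLES
    if encoding == "dummy_expanded":
        terms: list[str] = []
        for name in MODEL_VARIABLES:
            if name == "age":
                terms.append("age")
            else:
                for level in VARIABLES[name].levels[1:]:
                    terms.append(f"{name}[{level}]")
        return tuple(terms)
    raise ValueError(f"unknown encoding {encoding!r}")


def encode(records: pd.DataFrame, encoding: str) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) for a cohort frame."""
    terms = encoding_terms(encoding)
    out = pd.DataFrame(index=records.index)
    if encoding == "single_score":
        for name in MODEL_VARIABLES:
            if name == "age":
                out[name] = records["age"].astype(float)
            else:
                out[name] = records[name].map(SINGLE_SCORES[name]).astype(float)
    else:
        out["_"] = 0.0  # placeholder to set row index; removed below
        for name in MODEL_VARIABLES:
            if name == "age":
                out["age"] = records["age"].astype(float)
            else:
                for level in VARIABLES[name].levels[1:]:
                    out[f"{name}[{level}]"] = (records[name] == level).astype(float)
        out = out.drop(columns="_")
    return out[list(terms)]


@dataclass
class PredictionModel:
    """Intercept + coefficient vector on the log-odds scale.

    ``provenance`` distinguishes models fitted in-session (``fitted``)
    from the published equations shipped as fixtures
    (``printed_equation``).
    """

    intercept: float
    terms: tuple[str, ...]
    coef: np.ndarray
    encoding: str
    scheme: str = "plain"
    provenance: str = "fitted"
    se: np.ndarray | None = None
    converged: bool = True
    separation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (len(self.terms),):
            raise ValueError("coefficient vector length must match terms")
        if self.terms != encoding_terms(self.encoding):
            raise ValueError(
                f"terms do not match the {self.encoding!r} encoding dimension"
            )
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coef.tolist()))

    def linear_predictor(self, x) -> np.ndarray:
        X = self._as_matrix(x)
        return self.intercept + X @ self.coef

    def _as_matrix(self, x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            if tuple(x.columns) == self.terms:
                return x.to_numpy(dtype=float)
            return encode(x, self.encoding).to_numpy(dtype=float)
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        if arr.shape[1] != len(self.terms):
            raise ValueError(
                f"expected {len(self.terms)} covariates ({self.encoding}), "
                f"got {arr.shape[1]}"
            )
        return arr

    def to_dict(self) -> dict:
        d = {
            "intercept": self.intercept,
            "coefficients": self.coefficients(),
            "encoding": self.encoding,
            "scheme": self.scheme,
            "provenance": self.provenance,
            "converged": self.converged,
            "separation": list(self.separation),
        }
        if self.se is not None:
            d["se"] = dict(zip(self.terms, np.asarray(self.se).tolist()))
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PredictionModel":
        terms = encoding_terms(d["encoding"])
        coefs = d["coefficients"]
        se = d.get("se")
        return cls(
            intercept=float(d["intercept"]),
            terms=terms,
            coef=np.array([coefs[t] for t in terms], dtype=float),
            encoding=d["encoding"],
            scheme=d.get("scheme", "plain"),
            provenance=d.get("provenance", "fitted"),
            se=np.array([se[t] for t in terms]) if se else None,
            converged=bool(d.get("converged", True)),
            separation=tuple(d.get("separation", ())),
        )

    @classmethod
    def from_json(cls, path) -> "PredictionModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def predict_probability(model: PredictionModel, covariates) -> np.ndarray | float:
    """Logistic response 1 / (1 + exp(-(b0 + b.x))) for each row.

    ``covariates`` may be a cohort DataFrame (encoded per the model), an
    already-encoded design frame, or a raw vector/matrix in term order.
    Scalar input returns a scalar.
    """
    eta = model.linear_predictor(covariates)
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p[0]) if np.ndim(covariates) == 1 and p.size == 1 else p


def classify(probability, threshold: float = 0.5):
    """Label 1 iff probability >= threshold (ties classify positive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be strictly inside (0, 1)")
    p = np.asarray(probability, dtype=float)
    out = (p >= threshold).astype(np.int64)
    return int(out) if np.ndim(probability) == 0 else out
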
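"""Synthetic case-control cohort generation.

The generator emulates the marginal structure of the published screening
cohort: fixed group sizes (895 controls / 884 AIS cases), per-variable
category frequencies conditional on AIS status, and group-specific
truncated-normal ages.  Only marginal-by-status distributions are
published, so the baseline sampling model is conditional independence of
the variables given AIS status — the weakest assumption consistent with
the published tables.  An optional Gaussian-copula latent correlation
matrix can induce within-group dependence for stress-testing multivariate
fits.

One integer seed drives the whole cohort; no global random state is
touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .variables import (
    AGE_SUMMARY,
    CATEGORICAL_VARIABLES,
    GROUP_SIZES,
    RECORD_COLUMNS,
    TABLE1_COUNTS,
    VARIABLES,
)

__all__ = [
    "GroupValues",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "save_spec",
    "load_spec",
]

#: Age support in years: 1st through 12th graders.
AGE_BOUNDS = (6.0, 19.0)

#: Default seed for ``default_spec`` (chosen once; any integer works).
DEFAULT_SEED = 20190901

#: Variable order used by the latent-correlation (dependence) matrix:
#: every categorical variable in record order, then age last.
DEPENDENCE_ORDER: tuple[str, ...] = CATEGORICAL_VARIABLES + ("age",)


class GroupValues(NamedTuple):
    """A (control, case) pair of per-group values."""

    control: tuple
    case: tuple


def _probs_from_counts(counts: tuple[tuple[int, int], ...]) -> GroupValues:
    arr = np.asarray(counts, dtype=float)
    control = arr[:, 0] / arr[:, 0].sum()
    case = arr[:, 1] / arr[:, 1].sum()
    return GroupValues(tuple(map(float, control)), tuple(map(float, case)))


@dataclass
class CohortSpec:
    """Parameters of a synthetic screening cohort.

    Parameters
    ----------
    n_controls, n_cases
        Exact group sizes (non-negative).
    category_probs
        Mapping ``variable -> GroupValues(control_probs, case_probs)``
        over that variable's levels, in the level order declared in
        :data:`~scolioscreen.variables.VARIABLES`.
    age_params
        ``GroupValues((mean, sd), (mean, sd))`` in years.
    dependence
        Optional latent correlation matrix over :data:`DEPENDENCE_ORDER`
        (symmetric, unit diagonal, positive semi-definite).  ``None``
        means conditional independence given AIS status.
    seed
        Integer seed governing the entire cohort draw.
    """

    n_controls: int
    n_cases: int
    category_probs: Mapping[str, GroupValues]
    age_params: GroupValues
    dependence: np.ndarray | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_cases < 0:
            raise ValueError("group sizes must be non-negative")
        for name, probs in self.category_probs.items():
            if name not in VARIABLES:
                raise ValueError(f"unknown variable {name!r}")
            n_levels = len(VARIABLES[name].levels)
            for group, vec in zip(("control", "case"), probs):
                v = np.asarray(vec, dtype=float)
                if v.shape != (n_levels,):
                    raise ValueError(
                        f"{name}/{group}: expected {n_levels} probabilities, got {v.shape}"
                    )
                if (v < 0).any():
                    raise ValueError(f"{name}/{group}: negative probability")
                if abs(v.sum() - 1.0) > 1e-12:
                    raise ValueError(f"{name}/{group}: probabilities sum to {v.sum()!r}, not 1")
        missing = set(CATEGORICAL_VARIABLES) - set(self.category_probs)
        if missing:
            raise ValueError(f"category_probs missing variables: {sorted(missing)}")
        for mean, sd in self.age_params:
            if sd <= 0:
                raise ValueError("age sd must be positive")
        if self.dependence is not None:
            R = np.asarray(self.dependence, dtype=float)
            k = len(DEPENDENCE_ORDER)
            if R.shape != (k, k):
                raise ValueError(f"dependence matrix must be {k}x{k} over {DEPENDENCE_ORDER}")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError("dependence matrix must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ValueError("dependence matrix must have unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise ValueError("dependence matrix must be positive semi-definite")


def default_spec(seed: int = DEFAULT_SEED) -> CohortSpec:
    """Spec reproducing the published cohort's marginal structure.

    Group sizes 895/884, category probabilities equal to the published
    per-level counts divided by group totals, ages (12.67, 1.96) /
    (13.14, 1.87) years, no dependence.
    """
    return CohortSpec(
        n_controls=GROUP_SIZES[0],
        n_cases=GROUP_SIZES[1],
        category_probs={
            name: _probs_from_counts(counts) for name, counts in TABLE1_COUNTS.items()
        },
        age_params=GroupValues(AGE_SUMMARY["control"], AGE_SUMMARY["case"]),
        dependence=None,
        seed=seed,
    )


def _truncnorm(mean: float, sd: float) -> stats.rv_continuous:
    lo, hi = AGE_BOUNDS
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def _draw_group(
    spec: CohortSpec, group_idx: int, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    mean, sd = spec.age_params[group_idx]
    cols: dict[str, np.ndarray] = {}
    if spec.dependence is None:
        cols["age"] = _truncnorm(mean, sd).ppf(rng.random(n))
        for name in CATEGORICAL_VARIABLES:
            probs = np.asarray(spec.category_probs[name][group_idx], dtype=float)
            levels = np.asarray(VARIABLES[name].levels, dtype=object)
            cols[name] = levels[rng.choice(len(levels), size=n, p=probs)]
    else:
        # Gaussian copula: correlated latent normals mapped through each
        # variable's categorical thresholds (age through the truncated
        # normal quantile function).
        R = np.asarray(spec.dependence, dtype=float)
        w, V = np.linalg.eigh(R)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        z = rng.standard_normal((n, len(DEPENDENCE_ORDER))) @ L.T
        u = stats.norm.cdf(z)
        for j, name in enumerate(DEPENDENCE_ORDER):
            if name == "age":
                cols["age"] = _truncnorm(mean, sd).ppf(u[:, j])
            else:
                probs = np.asarray(spec.category_probs[name][group_idx], dtype=float)
                cuts = np.cumsum(probs)[:-1]
                idx = np.searchsorted(cuts, u[:, j], side="right")
                cols[name] = np.asarray(VARIABLES[name].levels, dtype=object)[idx]
    cols["ais"] = np.full(n, group_idx, dtype=np.int64)
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a full cohort: controls first (ais=0), then cases (ais=1).

    Group sizes are exact.  Given AIS status, each categorical variable is
    drawn from its group's probability vector (independently, or through
    the Gaussian copula when a dependence matrix is set); age is drawn
    from a normal truncated to 6–19 years.  The same spec (including its
    seed) always yields an identical DataFrame.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    parts = [
        _draw_group(spec, 0, spec.n_controls, rng),
        _draw_group(spec, 1, spec.n_cases, rng),
    ]
    df = pd.concat(parts, ignore_index=True) if (spec.n_controls or spec.n_cases) else parts[0]
    if df.empty:
        return pd.DataFrame(columns=list(RECORD_COLUMNS))
    return df[list(RECORD_COLUMNS)]


# ---------------------------------------------------------------------------
# Spec (de)serialization — JSON or YAML by file suffix.

def _spec_to_dict(spec: CohortSpec) -> dict:
    d = {
        "n_controls": spec.n_controls,
        "n_cases": spec.n_cases,
        "category_probs": {
            name: {
                "control": [float(x) for x in p.control],
                "case": [float(x) for x in p.case],
            }
            for name, p in spec.category_probs.items()
        },
        "age_params": {
            "control": [float(x) for x in spec.age_params.control],
            "case": [float(x) for x in spec.age_params.case],
        },
        "seed": spec.seed,
    }
    if spec.dependence is not None:
        d["dependence"] = np.asarray(spec.dependence).tolist()
    return d


def _spec_from_dict(d: dict) -> CohortSpec:
    return CohortSpec(
        n_controls=int(d["n_controls"]),
        n_cases=int(d["n_cases"]),
        category_probs={
            name: GroupValues(tuple(v["control"]), tuple(v["case"]))
            for name, v in d["category_probs"].items()
        },
        age_params=GroupValues(
            tuple(d["age_params"]["control"]), tuple(d["age_params"]["case"])
        ),
        dependence=np.asarray(d["dependence"]) if "dependence" in d else None,
        seed=int(d.get("seed", DEFAULT_SEED)),
    )


def save_spec(spec: CohortSpec, path) -> None:
    """Write a spec as JSON (``.json``) or YAML (anything else)."""
    d = _spec_to_dict(spec)
    text = (
        json.dumps(d, indent=2, sort_keys=True)
        if str(path).endswith(".json")
        else yaml.safe_dump(d, sort_keys=True)
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def load_spec(path) -> CohortSpec:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return _spec_from_dict(d)


def with_sizes(spec: CohortSpec, n_controls: int, n_cases: int) -> CohortSpec:
    """Copy of *spec* with different group sizes (probabilities unchanged)."""
    return replace(spec, n_controls=n_controls, n_cases=n_cases)
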
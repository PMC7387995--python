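"""Variable registry and reference summary tables for the screening cohort.

The study design is a school-scoliosis-screening case-control comparison:
895 non-AIS controls (radiographic Cobb angle < 10°) versus 884 AIS cases
(Cobb angle >= 10°).  Each subject carries demographic fields (gender, age,
school category) and nine postural signs assessed by visual inspection,
Adam's forward-bending test and scoliometer measurement of the angle of
trunk rotation (ATR; an ATR > 5° is the abnormality cut-off).

``TABLE1_COUNTS`` holds the published per-level counts by AIS status for
every categorical variable.  They serve two roles: default parameters for
the synthetic-cohort generator, and fixture inputs for the worked examples
(chi-square statistics, odds ratios, grouped AUCs) that the published
analysis reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "VariableDef",
    "VARIABLES",
    "CATEGORICAL_VARIABLES",
    "MODEL_VARIABLES",
    "RECORD_COLUMNS",
    "SINGLE_SCORES",
    "TABLE1_COUNTS",
    "AGE_SUMMARY",
    "GROUP_SIZES",
    "PUBLISHED_CHI2",
    "PUBLISHED_AUC",
    "GROUP_LABELS",
]


@dataclass(frozen=True)
class VariableDef:
    """One screening variable: its canonical name, level labels and kind."""

    name: str
    levels: tuple[str, ...]
    kind: str  # "demographic" | "posture" | "atr" | "continuous"
    label: str

    @property
    def reference(self) -> str:
        """Reference (baseline) level — always the first listed."""
        return self.levels[0]


_LATERAL = ("normal", "left", "right")
_BINARY = ("normal", "abnormal")
_ATR = ("normal_0_5", "left_gt5", "right_gt5")

#: All categorical variables in record-column order.  The first level of
#: each is the reference category used by the association models.
VARIABLES: Mapping[str, VariableDef] = {
    v.name: v
    for v in (
        VariableDef("gender", ("boy", "girl"), "demographic", "Gender"),
        VariableDef("school", ("primary", "junior", "senior"), "demographic", "School category"),
        VariableDef("shoulder_height_diff", _LATERAL, "posture", "Shoulder-height difference"),
        VariableDef("scapular_tilt", _LATERAL, "posture", "Scapular tilt"),
        VariableDef("lumbar_concave", _LATERAL, "posture", "Lumbar concave"),
        VariableDef("pelvic_tilt", _LATERAL, "posture", "Pelvic tilt"),
        VariableDef("flat_back", _BINARY, "posture", "Flat back"),
        VariableDef("thoracic_kyphosis", _BINARY, "posture", "Thoracic kyphosis"),
        VariableDef("lumbar_kyphosis", _BINARY, "posture", "Lumbar kyphosis"),
        VariableDef("atr_thoracic", _ATR, "atr", "Angle of thoracic rotation"),
        VariableDef("atr_thoracolumbar", _ATR, "atr", "Angle of thoracolumbar rotation"),
        VariableDef("atr_lumbar", _ATR, "atr", "Angle of lumbar rotation"),
    )
}

CATEGORICAL_VARIABLES: tuple[str, ...] = tuple(VARIABLES)

#: The twelve model covariates X1..X12 in their canonical order.  School
#: category is descriptive only and never enters a model.
MODEL_VARIABLES: tuple[str, ...] = (
    "gender",
    "age",
    "shoulder_height_diff",
    "scapular_tilt",
    "lumbar_concave",
    "pelvic_tilt",
    "flat_back",
    "thoracic_kyphosis",
    "lumbar_kyphosis",
    "atr_thoracic",
    "atr_thoracolumbar",
    "atr_lumbar",
)

#: Column contract for a cohort DataFrame / CSV file.
RECORD_COLUMNS: tuple[str, ...] = (
    "gender",
    "age",
    "school",
    "shoulder_height_diff",
    "scapular_tilt",
    "lumbar_concave",
    "pelvic_tilt",
    "flat_back",
    "thoracic_kyphosis",
    "lumbar_kyphosis",
    "atr_thoracic",
    "atr_thoracolumbar",
    "atr_lumbar",
    "ais",
)

#: Single-number ("single_score") coding of each categorical model
#: covariate: reference level 0, then 1, 2 in listed level order.  Age
#: enters as raw years.
SINGLE_SCORES: Mapping[str, Mapping[str, int]] = {
    name: {level: i for i, level in enumerate(VARIABLES[name].levels)}
    for name in CATEGORICAL_VARIABLES
}

GROUP_LABELS: tuple[str, str] = ("control", "case")

#: Published per-level counts, (control, case) per level in level order.
#: Column totals are the group sizes 895 / 884 (N = 1779).
TABLE1_COUNTS: Mapping[str, tuple[tuple[int, int], ...]] = {
    "gender": ((572, 311), (323, 573)),
    "school": ((359, 239), (374, 458), (162, 187)),
    "shoulder_height_diff": ((779, 410), (73, 252), (43, 222)),
    "scapular_tilt": ((764, 268), (85, 349), (46, 267)),
    "lumbar_concave": ((814, 450), (31, 181), (50, 253)),
    "pelvic_tilt": ((860, 694), (23, 68), (12, 122)),
    "flat_back": ((893, 875), (2, 9)),
    "thoracic_kyphosis": ((886, 851), (9, 33)),
    "lumbar_kyphosis": ((891, 882), (4, 2)),
    "atr_thoracic": ((853, 565), (18, 90), (24, 229)),
    "atr_thoracolumbar": ((872, 796), (9, 42), (14, 46)),
    "atr_lumbar": ((816, 511), (61, 277), (18, 96)),
}

#: Age mean ± SD (years) by group.
AGE_SUMMARY: Mapping[str, tuple[float, float]] = {
    "control": (12.67, 1.96),
    "case": (13.14, 1.87),
}

#: (n_controls, n_cases)
GROUP_SIZES: tuple[int, int] = (895, 884)

#: Published chi-square statistics by variable (Yates-corrected where the
#: published table flags it — lumbar kyphosis).
PUBLISHED_CHI2: Mapping[str, float] = {
    "gender": 146.84,
    "school": 34.29,
    "shoulder_height_diff": 333.96,
    "scapular_tilt": 554.97,
    "lumbar_concave": 346.90,
    "pelvic_tilt": 130.22,
    "flat_back": 4.57,
    "thoracic_kyphosis": 14.35,
    "lumbar_kyphosis": 0.16,
    "atr_thoracic": 272.54,
    "atr_thoracolumbar": 41.82,
    "atr_lumbar": 261.45,
}

#: Published per-predictor AUCs (binary-collapse ROC for categorical
#: variables, binormal for age).  Flat back, thoracic kyphosis and lumbar
#: kyphosis were not reported (no significant discrimination).
PUBLISHED_AUC: Mapping[str, float] = {
    "gender": 0.65,
    "age": 0.57,
    "shoulder_height_diff": 0.70,
    "scapular_tilt": 0.77,
    "lumbar_concave": 0.71,
    "pelvic_tilt": 0.59,
    "atr_thoracic": 0.66,
    "atr_thoracolumbar": 0.54,
    "atr_lumbar": 0.67,
}
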
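"""Train/test evaluation protocol and confusion-matrix battery.

The protocol mirrors a standard screening-model validation: a stratified
7:3 random split, a multivariate logistic fit on the training part, the
three coefficient-weighted variants derived from the same training data,
and sensitivity / specificity / Youden's index / predictive values /
total accuracy measured on the held-out test part at a fixed probability
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import fit_multivariate
from .model import PredictionModel, SCHEMES, classify, predict_probability
from .weighting import aor_weights, auc_weights, apply_weighting, scheme_weights

__all__ = [
    "ConfusionMetrics",
    "split_cohort",
    "confusion_metrics",
    "evaluate_models",
    "table3_report",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 prediction-table counts and the derived screening metrics.

    Rates are on the proportion scale; ``as_percent_dict`` formats them
    the way screening reports print them.  Undefined ratios (zero
    denominator) are NaN, never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def se(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def sp(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def ac(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return self._ratio(self.tp + self.tn, total)

    @property
    def yi(self) -> float:
        """Youden's index, sensitivity + specificity - 1."""
        return self.se + self.sp - 1.0

    def as_percent_dict(self) -> dict[str, float]:
        return {
            "Se": round(100 * self.se, 2),
            "Sp": round(100 * self.sp, 2),
            "YI": round(self.yi, 2),
            "PPV": round(100 * self.ppv, 2),
            "NPV": round(100 * self.npv, 2),
            "Ac": round(100 * self.ac, 2),
        }


def confusion_metrics(true_labels, predicted_labels) -> ConfusionMetrics:
    """Exact counts from equal-length 0/1 label vectors."""
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    if y.shape != yhat.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", y), ("predicted", yhat)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} labels must be 0 or 1")
    return ConfusionMetrics(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
    )


def split_cohort(
    records: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int | None = None,
    stratify: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test partition of exact size round(f * n) / remainder.

    Stratified by the AIS label by default so both parts keep the case
    fraction (sizes then round within each stratum).  Seed-reproducible;
    ``train_fraction`` must leave both parts non-empty.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[np.ndarray] = []
        for _, grp in records.groupby("ais", sort=True):
            perm = grp.index.to_numpy()[rng.permutation(len(grp))]
            k = round(train_fraction * len(grp))
            train_idx.append(perm[:k])
        chosen = np.concatenate(train_idx)
    else:
        perm = records.index.to_numpy()[rng.permutation(n)]
        chosen = perm[: round(train_fraction * n)]
    mask = records.index.isin(chosen)
    train, test = records.loc[mask], records.loc[~mask]
    if train.empty or test.empty:
        raise ValueError("split leaves an empty partition; adjust train_fraction")
    return train, test


def evaluate_models(
    cohort: pd.DataFrame,
    schemes: tuple[str, ...] = SCHEMES,
    seed: int | None = None,
    train_fraction: float = 0.7,
    threshold: float = 0.5,
) -> dict[str, ConfusionMetrics]:
    """Fit on the training split, score each scheme on the test split.

    The plain model is a single-score multivariate fit; AOR weights come
    from a dummy-encoded fit on the same training data, AUC weights from
    training-split per-predictor ROC areas, and the combined scheme from
    their product.  Classification at ``threshold`` (default 0.5).
    Returns one ConfusionMetrics per requested scheme.
    """
    if cohort["ais"].nunique() < 2:
        raise ValueError("cohort must contain both classes")
    train, test = split_cohort(cohort, train_fraction, seed=seed)
    plain = fit_multivariate(train, encoding="single_score")
    models: dict[str, PredictionModel] = {"plain": plain}
    weighted = set(schemes) - {"plain"}
    if weighted:
        w_aor = aor_weights(fit_multivariate(train, encoding="dummy_expanded"), train)
        w_auc = auc_weights(train)
        for scheme in weighted:
            models[scheme] = apply_weighting(
                plain, scheme_weights(scheme, w_aor, w_auc), scheme, train
            )
    out: dict[str, ConfusionMetrics] = {}
    y_test = test["ais"].to_numpy()
    for scheme in schemes:
        p = predict_probability(models[scheme], test)
        out[scheme] = confusion_metrics(y_test, classify(p, threshold))
    return out


def table3_report(metrics: dict[str, ConfusionMetrics]) -> pd.DataFrame:
    """Metric battery as rows (Se/Sp/YI/PPV/NPV/Ac), schemes as columns."""
    cols = {scheme: m.as_percent_dict() for scheme, m in metrics.items()}
    return pd.DataFrame(cols)
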
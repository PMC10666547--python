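"""Scoring and comparison of category predictions and regression output."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categorization import ToxicityCategorySchema

__all__ = [
    "ComparisonReport",
    "confusion",
    "r_squared",
    "pearson",
    "residual_summary",
    "agreement_fraction",
    "comparison_report",
]


def confusion(true_labels: Sequence, predicted_labels: Sequence,
              schema: ToxicityCategorySchema | Sequence[str]
              ) -> tuple[pd.DataFrame, int]:
    """Confusion matrix (rows = true, columns = predicted) + misclassified count."""
    labels = list(schema.labels) if isinstance(schema, ToxicityCategorySchema) else list(schema)
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    unknown = set(t.tolist()) | set(p.tolist())
    unknown -= set(labels)
    if unknown:
        raise ValueError(f"label(s) not in schema: {sorted(unknown)}")
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(t, p):
        mat[idx[a], idx[b]] += 1
    df = pd.DataFrame(mat, index=labels, columns=labels)
    return df, int(len(t) - np.trace(mat))


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("vectors differ in length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("vectors differ in length")
    if xv.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(xv, yv)[0, 1])


def residual_summary(observed: Sequence[float], predicted: Sequence[float],
                     band: float = 1.0) -> dict:
    """Residual (observed - predicted) spread summary.

    Returns the fraction of absolute residuals within ``band`` log units
    plus residual quantiles.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("vectors differ in length")
    res = obs - pred
    qs = (0.025, 0.25, 0.5, 0.75, 0.975)
    return {
        "band": float(band),
        "fraction_within_band": float(np.mean(np.abs(res) <= band)) if res.size else 1.0,
        "quantiles": {f"q{q:g}": float(np.quantile(res, q)) for q in qs} if res.size else {},
    }


def agreement_fraction(labels_a: Sequence, labels_b: Sequence) -> float:
    """Fraction of positions where two label vectors agree."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(a == b))


@dataclass
class ComparisonReport:
    """Classification scorecard for one prediction method."""

    confusion: pd.DataFrame
    misclassified: int
    accuracy: float
    per_category_recall: dict[str, float]
    agreement_with: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": {a: {b: int(v) for b, v in row.items()}
                          for a, row in self.confusion.to_dict("index").items()},
            "misclassified": self.misclassified,
            "accuracy": self.accuracy,
            "per_category_recall": self.per_category_recall,
            "agreement_with": self.agreement_with,
        }


def comparison_report(true_labels: Sequence, predicted_labels: Sequence,
                      schema: ToxicityCategorySchema | Sequence[str],
                      other_methods: Mapping[str, Sequence] | None = None
                      ) -> ComparisonReport:
    """Score one method's predictions and its agreement with other methods."""
    mat, mis = confusion(true_labels, predicted_labels, schema)
    n = int(mat.to_numpy().sum())
    recall = {}
    for lab in mat.index:
        row_total = int(mat.loc[lab].sum())
        recall[lab] = float(mat.loc[lab, lab] / row_total) if row_total else float("nan")
    agreement = {name: agreement_fraction(predicted_labels, other)
                 for name, other in (other_methods or {}).items()}
    return ComparisonReport(confusion=mat, misclassified=mis,
                            accuracy=float((n - mis) / n) if n else float("nan"),
                            per_category_recall=recall, agreement_with=agreement)
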
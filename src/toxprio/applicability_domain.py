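"""Leverage-based applicability-domain (AD) assessment.

The leverage of a query chemical with descriptor vector x against a
training matrix X is h = x' (X'X)^- x, the hat-matrix diagonal: a
squared Mahalanobis-like distance from the centre of the training cloud.
Chemicals with h above a warning threshold (default h* = 3p/n, capped at
1) are flagged as outside the domain — predictions for them are
extrapolations.  The AD can be evaluated over several descriptor
subspaces (the full curated space, or just the variables a model uses)
and the resulting in/out flags compared.

When p > n (the full curated space can have more descriptors than
training chemicals) X'X is singular, so a Moore-Penrose generalized
inverse with a singular-value cutoff is used; for full-rank X'X it
coincides with the ordinary inverse.  Reports flag this regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LeverageModel",
    "ADReport",
    "build_leverage_model",
    "leverage",
    "leverages",
    "ad_assess",
    "ad_compare",
]


@dataclass
class LeverageModel:
    """Training matrix summary needed to compute query leverages."""

    subset_name: str
    columns: list[str] | None
    xtx_pinv: np.ndarray  # (p, p) generalized inverse of X'X
    n: int
    p: int
    rank: int
    threshold: float

    @property
    def rank_deficient(self) -> bool:
        return self.rank < self.p


def build_leverage_model(X_train: pd.DataFrame | np.ndarray,
                         subset_name: str = "all",
                         threshold: float | None = None,
                         rcond: float = 1e-10) -> LeverageModel:
    """Precompute (X'X)^- and the warning threshold for one subspace.

    ``threshold`` defaults to min(3p/n, 1), the standard warning leverage
    of Williams plots.  A generalized (pseudo-)inverse with singular-value
    cutoff ``rcond`` handles rank-deficient X'X; for full-rank matrices it
    equals the ordinary inverse.
    """
    columns = list(X_train.columns) if isinstance(X_train, pd.DataFrame) else None
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("training matrix must be a nonempty 2-D array")
    n, p = X.shape
    G = X.T @ X
    P = np.linalg.pinv(G, rcond=rcond, hermitian=True)
    P = (P + P.T) / 2.0  # enforce exact symmetry
    rank = int(np.linalg.matrix_rank(X))
    if threshold is None:
        threshold = min(3.0 * p / n, 1.0)
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    return LeverageModel(subset_name=subset_name, columns=columns,
                         xtx_pinv=P, n=n, p=p, rank=rank, threshold=float(threshold))


def leverage(model: LeverageModel, x: Sequence[float]) -> float:
    """Leverage h = x' (X'X)^- x of one query vector (same scaling as training)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.p,):
        raise ValueError(f"expected a length-{model.p} vector, got shape {x.shape}")
    return float(max(x @ model.xtx_pinv @ x, 0.0))


def leverages(model: LeverageModel, X: np.ndarray) -> np.ndarray:
    """Row-wise leverages of a query matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.p:
        raise ValueError(f"expected {model.p} columns, got {X.shape[1]}")
    h = np.einsum("ij,jk,ik->i", X, model.xtx_pinv, X)
    return np.clip(h, 0.0, None)


@dataclass
class ADReport:
    """Per-chemical leverages and in/out-of-domain flags for one subspace."""

    subset_name: str
    threshold: float
    table: pd.DataFrame  # index: chemical id; columns: leverage, in_domain
    rank_deficient: bool = False

    @property
    def n_in(self) -> int:
        return int(self.table["in_domain"].sum())

    @property
    def n_out(self) -> int:
        return int(len(self.table) - self.n_in)

    def summary(self) -> dict:
        return {"subset": self.subset_name, "threshold": self.threshold,
                "n": int(len(self.table)), "n_in": self.n_in, "n_out": self.n_out,
                "rank_deficient_gram_matrix": self.rank_deficient}

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, float_format="%.12g")


def ad_assess(model: LeverageModel, table) -> ADReport:
    """Assess every chemical in ``table`` against one leverage model.

    ``table`` may be a DescriptorTable, a DataFrame indexed by id, or a
    bare matrix.  In-domain means h <= threshold.
    """
    data = getattr(table, "data", table)
    if isinstance(data, pd.DataFrame):
        if model.columns is not None:
            missing = [c for c in model.columns if c not in data.columns]
            if missing:
                raise KeyError(f"query table lacks column(s): {missing}")
            data = data.loc[:, model.columns]
        index = data.index
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    h = leverages(model, X)
    out = pd.DataFrame({"leverage": h, "in_domain": h <= model.threshold}, index=index)
    return ADReport(subset_name=model.subset_name, threshold=model.threshold,
                    table=out, rank_deficient=model.rank < model.p)


def ad_compare(reports: Sequence[ADReport]) -> dict:
    """Summarise several subspace ADs over the same chemicals.

    Returns per-subset in/out counts plus a pairwise flag-agreement
    matrix (fraction of chemicals with identical in/out decisions).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    ids = list(reports[0].table.index)
    for r in reports[1:]:
        if list(r.table.index) != ids:
            raise ValueError("reports do not cover identical chemicals")
    names = [r.subset_name for r in reports]
    if len(set(names)) != len(names):
        raise ValueError("subset names must be unique for comparison")
    flags = {r.subset_name: r.table["in_domain"].to_numpy() for r in reports}
    agreement = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            agreement.loc[a, b] = float(np.mean(flags[a] == flags[b]))
    return {
        "n": len(ids),
        "counts": {r.subset_name: {"in": r.n_in, "out": r.n_out} for r in reports},
        "agreement": agreement,
        "rank_deficient": {r.subset_name: r.rank_deficient for r in reports},
    }


def compare_to_json(comparison: dict, path: str | Path) -> None:
    payload = dict(comparison)
    payload["agreement"] = {a: {b: float(v) for b, v in row.items()}
                            for a, row in comparison["agreement"].to_dict("index").items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
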
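"""Toxicity category schemas: bootstrapped k-means and GHS thresholds.

Two ways of turning an acute fish 96 h LC50 into a hazard category are
supported.  The data-driven route clusters chemicals by k-means on
(log10 LC50 in mg/L, monoisotopic mass in Da), stabilised by bootstrap:
the training split is resampled with replacement many times, k-means is
refit on each resample, the per-iteration centroid sets are aligned by
sorting on the log-LC50 coordinate, and the most frequently recurring
(rounded) centroid set becomes the final model.  The regulatory route
applies the GHS short-term aquatic hazard thresholds: acute 1 for
LC50 <= 1 mg/L, acute 2 for 1 < LC50 <= 10 mg/L, acute 3 above 10 mg/L.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import NotFittedError

__all__ = [
    "UNIT_TO_MG_PER_L",
    "GHS_LABELS",
    "GHS_THRESHOLDS_MG_PER_L",
    "KMEANS_DEFAULT_LABELS",
    "to_mg_per_l",
    "to_log_mg_per_l",
    "assign_ghs",
    "ToxicityCategorySchema",
    "ghs_schema",
    "KMeansCategorizer",
    "fit_kmeans_categorizer",
    "select_modal_centroids",
    "assign_kmeans",
]

UNIT_TO_MG_PER_L = {
    "g/L": 1e3,
    "mg/L": 1.0,
    "μg/L": 1e-3,
    "µg/L": 1e-3,  # micro sign variant
    "ug/L": 1e-3,
    "ng/L": 1e-6,
}

#: GHS short-term (acute) aquatic hazard classes, most toxic first.
GHS_LABELS = ("acute 1", "acute 2", "acute 3")
GHS_THRESHOLDS_MG_PER_L = (1.0, 10.0)

#: Default labels for a 4-cluster k-means schema, most toxic first.
KMEANS_DEFAULT_LABELS = ("high toxicity", "moderate toxicity",
                         "low toxicity", "very low toxicity")


def to_mg_per_l(value: float, unit: str) -> float:
    if unit not in UNIT_TO_MG_PER_L:
        raise ValueError(f"unknown concentration unit {unit!r}")
    if not value > 0:
        raise ValueError(f"concentration must be > 0, got {value}")
    return value * UNIT_TO_MG_PER_L[unit]


def to_log_mg_per_l(value: float, unit: str = "mg/L") -> float:
    """Convert a concentration to log10(mg/L). E.g. 0.95 μg/L -> -3.02."""
    return math.log10(to_mg_per_l(value, unit))


def assign_ghs(lc50_mg_per_l: float) -> str:
    """GHS acute aquatic hazard class for a 96 h LC50 in mg/L.

    Boundaries are inclusive on the more-toxic side: exactly 1 mg/L is
    acute 1 and exactly 10 mg/L is acute 2.
    """
    if not lc50_mg_per_l > 0:
        raise ValueError(f"LC50 must be > 0 mg/L, got {lc50_mg_per_l}")
    if lc50_mg_per_l <= GHS_THRESHOLDS_MG_PER_L[0]:
        return GHS_LABELS[0]
    if lc50_mg_per_l <= GHS_THRESHOLDS_MG_PER_L[1]:
        return GHS_LABELS[1]
    return GHS_LABELS[2]


@dataclass
class KMeansCategorizer:
    """A fitted, bootstrap-stabilised k-means toxicity categorizer.

    Centroids live in z-scored (log10 LC50 mg/L, monoisotopic mass Da)
    space and are ordered ascending by their log-LC50 coordinate, so the
    first label is the most toxic cluster.
    """

    centroids: np.ndarray  # (k, 2), standardized space
    feature_means: np.ndarray  # (2,)
    feature_sds: np.ndarray  # (2,)
    labels: tuple[str, ...]
    holdout_agreement: float | None = None
    n_boot: int = 0
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def centroids_raw(self) -> np.ndarray:
        """Centroids destandardized back to (log LC50, mass) units."""
        return self.centroids * self.feature_sds + self.feature_means

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "labels": list(self.labels),
            "centroids_standardized": self.centroids.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "holdout_agreement": self.holdout_agreement,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "KMeansCategorizer":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            centroids=np.asarray(d["centroids_standardized"], dtype=float),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            labels=tuple(d["labels"]),
            holdout_agreement=d.get("holdout_agreement"),
            n_boot=d.get("n_boot", 0),
            seed=d.get("seed"),
        )


@dataclass
class ToxicityCategorySchema:
    """Ordered toxicity category labels plus how they are assigned.

    ``provenance`` is "ghs" (fixed LC50 thresholds) or "kmeans" (nearest
    stored centroid in (log LC50, mass) space).  Labels are ordered most
    toxic first.
    """

    labels: tuple[str, ...]
    provenance: str
    thresholds_mg_per_l: tuple[float, ...] | None = None
    categorizer: KMeansCategorizer | None = None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("schema labels must be unique")
        if self.provenance == "ghs":
            if len(self.labels) != 3 or self.thresholds_mg_per_l != GHS_THRESHOLDS_MG_PER_L:
                raise ValueError("a GHS schema has 3 labels and thresholds (1, 10) mg/L")
        elif self.provenance == "kmeans":
            if self.categorizer is None or self.categorizer.k != len(self.labels):
                raise ValueError("a kmeans schema needs a categorizer with k == len(labels)")
        else:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def needs_mass(self) -> bool:
        return self.provenance == "kmeans"

    def assign(self, lc50_mg_per_l: float, mass: float | None = None) -> str:
        if self.provenance == "ghs":
            return assign_ghs(lc50_mg_per_l)
        if mass is None:
            raise ValueError("kmeans schema requires a monoisotopic mass")
        return assign_kmeans(self.categorizer, (math.log10(lc50_mg_per_l), mass))


def ghs_schema() -> ToxicityCategorySchema:
    """The built-in GHS acute aquatic hazard schema."""
    return ToxicityCategorySchema(labels=GHS_LABELS, provenance="ghs",
                                  thresholds_mg_per_l=GHS_THRESHOLDS_MG_PER_L)


def kmeans_schema(categorizer: KMeansCategorizer) -> ToxicityCategorySchema:
    return ToxicityCategorySchema(labels=categorizer.labels, provenance="kmeans",
                                  categorizer=categorizer)


def _sort_centroids(centroids: np.ndarray) -> np.ndarray:
    """Align a centroid set: ascending by log-LC50 coordinate, ties by mass."""
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    return centroids[order]


def select_modal_centroids(centroid_sets: Sequence[np.ndarray],
                           rounding: int = 2) -> np.ndarray:
    """Most frequently recurring centroid set across bootstrap refits.

    Sets (already aligned to a common label order) are compared after
    rounding to ``rounding`` decimals; the winning equivalence class is
    the most frequent one (ties broken toward the class seen earliest),
    and the returned centroids are the mean of its unrounded members.
    """
    if len(centroid_sets) == 0:
        raise ValueError("no centroid sets supplied")
    classes: dict[tuple, list[int]] = {}
    for i, cs in enumerate(centroid_sets):
        key = tuple(np.round(np.asarray(cs, dtype=float), rounding).ravel())
        classes.setdefault(key, []).append(i)
    best = max(classes.values(), key=lambda idx: (len(idx), -idx[0]))
    return np.mean([np.asarray(centroid_sets[i], dtype=float) for i in best], axis=0)


def fit_kmeans_categorizer(points: np.ndarray,
                           k: int = 4,
                           n_boot: int = 500,
                           train_frac: float = 0.9,
                           seed: int = 0,
                           labels: Sequence[str] | None = None,
                           rounding: int = 2,
                           n_init: int = 25,
                           tol: float = 1e-6,
                           max_iter: int = 300) -> KMeansCategorizer:
    """Fit a bootstrap-stabilised k-means toxicity categorizer.

    ``points`` is (n, 2): column 0 log10 LC50 (mg/L), column 1
    monoisotopic mass (Da).  The data are split train/test (``train_frac``),
    z-scored with the training mean/sd, and k-means is refit on ``n_boot``
    bootstrap resamples of the training split; the modal aligned centroid
    set becomes the final model.  ``holdout_agreement`` is the fraction of
    test points assigned to the same cluster by the modal centroids and by
    a single k-means fit on the full training split.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (log LC50, mass)")
    n = pts.shape[0]
    if np.unique(pts, axis=0).shape[0] < k:
        raise ValueError(f"need at least k={k} distinct points")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if labels is None:
        labels = KMEANS_DEFAULT_LABELS if k == 4 else tuple(f"category {i + 1}" for i in range(k))
    if len(labels) != k:
        raise ValueError(f"need {k} labels, got {len(labels)}")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, k), n)  # keep at least k points to cluster
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    train = pts[train_idx]

    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)
    z_train = (train - means) / sds

    def _fit(data: np.ndarray) -> np.ndarray:
        km = KMeans(n_clusters=k, n_init=n_init, tol=tol, max_iter=max_iter,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        km.fit(data)
        return _sort_centroids(km.cluster_centers_)

    reference = _fit(z_train)
    sets = []
    for _ in range(n_boot):
        boot = z_train[rng.integers(0, n_train, n_train)]
        if np.unique(boot, axis=0).shape[0] < k:
            continue  # degenerate resample: fewer distinct points than clusters
        sets.append(_fit(boot))
    final = _sort_centroids(select_modal_centroids(sets, rounding))

    cat = KMeansCategorizer(centroids=final, feature_means=means, feature_sds=sds,
                            labels=tuple(labels), n_boot=n_boot, seed=seed)
    if len(test_idx) > 0:
        z_test = (pts[test_idx] - means) / sds
        a = np.argmin(((z_test[:, None, :] - final[None]) ** 2).sum(-1), axis=1)
        b = np.argmin(((z_test[:, None, :] - reference[None]) ** 2).sum(-1), axis=1)
        cat.holdout_agreement = float(np.mean(a == b))
    return cat


def assign_kmeans(categorizer: KMeansCategorizer, point: Sequence[float]) -> str:
    """Label of the nearest centroid for a (log10 LC50 mg/L, mass Da) point.

    Ties go to the lower centroid index (the more toxic cluster).
    """
    if categorizer is None or getattr(categorizer, "centroids", None) is None:
        raise NotFittedError("categorizer is not fitted")
    z = (np.asarray(point, dtype=float) - categorizer.feature_means) / categorizer.feature_sds
    d2 = ((categorizer.centroids - z) ** 2).sum(axis=1)
    return categorizer.labels[int(np.argmin(d2))]
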
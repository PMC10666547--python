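"""Reusable synthetic benchmark experiments.

These experiments are the package's built-in evidence base: they measure,
on generated data with known ground truth, the behaviours the method is
designed around — that a bootstrapped k-means categorizer recovers
well-separated components, and that direct classification commits fewer
categorization errors than the two-step regression-then-threshold route
when the descriptor-to-toxicity map is discontinuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .categorization import assign_ghs, fit_kmeans_categorizer, ghs_schema
from .evaluation import confusion
from .modeling import (fit_final, predict_category_direct, split_train_test,
                       two_step_categorize)
from .synthetic_data import GeneratorConfig, generate_training, make_fixture

__all__ = ["DirectVsTwoStepResult", "direct_vs_two_step", "blob_recovery"]


@dataclass
class DirectVsTwoStepResult:
    """Per-seed test-set misclassification counts for both strategies."""

    two_step: list[int]
    direct: list[int]
    n_test: int
    n_seeds: int

    @property
    def direct_win_fraction(self) -> float:
        """Fraction of seeds where direct classification made strictly fewer errors."""
        return float(np.mean([d < t for t, d in zip(self.two_step, self.direct)]))

    @property
    def median_ratio(self) -> float:
        """Median over seeds of (two-step errors) / (direct errors)."""
        ratios = [t / d if d else np.inf for t, d in zip(self.two_step, self.direct)]
        return float(np.median(ratios))


def direct_vs_two_step(n_chemicals: int = 800, n_descriptors: int = 100,
                       n_seeds: int = 20, base_seed: int = 0,
                       n_trees: int = 400, min_leaf: int = 4,
                       train_frac: float = 0.9) -> DirectVsTwoStepResult:
    """Compare direct classification against regression-then-threshold.

    For each seed a discontinuous-response training set is generated, GHS
    labels are derived from the (noisy) generated LC50 values, both a
    regression and a classification forest are fitted at matched budgets
    on the same 90% split, and test-set misclassifications against the
    GHS labels are counted.
    """
    schema = ghs_schema()
    two_step_errors, direct_errors = [], []
    n_test = None
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = GeneratorConfig(n_chemicals=n_chemicals, n_descriptors=n_descriptors,
                              response="discontinuous", seed=seed)
        tr = generate_training(cfg)
        X, y = tr.table.data, tr.log_lc50
        labels = np.asarray([assign_ghs(r.lc50) for r in tr.records])
        tri, tei = split_train_test(n_chemicals, frac=train_frac, seed=seed)
        reg = fit_final(X.iloc[tri], y[tri], X.columns, n_trees, min_leaf,
                        "regression", seed=seed)
        clf = fit_final(X.iloc[tri], labels[tri], X.columns, n_trees, min_leaf,
                        "classification", seed=seed)
        two = two_step_categorize(reg, schema, X.iloc[tei])
        direct = predict_category_direct(clf, X.iloc[tei])
        _, mis_two = confusion(labels[tei], two, schema)
        _, mis_dir = confusion(labels[tei], direct, schema)
        two_step_errors.append(mis_two)
        direct_errors.append(mis_dir)
        n_test = len(tei)
    return DirectVsTwoStepResult(two_step=two_step_errors, direct=direct_errors,
                                 n_test=n_test, n_seeds=n_seeds)


def blob_recovery(n_boot: int = 500, seed: int = 0):
    """Fit the bootstrapped categorizer on the 4-blob fixture.

    Returns (categorizer, max standard-error distance): the largest
    |centroid - true component mean| / SE over all centroids and both
    coordinates, where SE is the component's per-dimension standard error
    of the mean.
    """
    fx = make_fixture("blobs4")
    cat = fit_kmeans_categorizer(fx.points, k=4, n_boot=n_boot, seed=seed)
    raw = cat.centroids_raw()
    worst = 0.0
    for i in range(4):
        comp = fx.points[fx.labels == i]
        se = comp.std(axis=0, ddof=1) / np.sqrt(len(comp))
        worst = max(worst, float(np.max(np.abs(raw[i] - comp.mean(axis=0)) / se)))
    return cat, worst
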
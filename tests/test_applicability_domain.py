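import numpy as np
import pandas as pd
import pytest

from toxprio.applicability_domain import (ad_assess, ad_compare,
                                          build_leverage_model, leverage,
                                          leverages)
from toxprio.synthetic_data import GeneratorConfig, generate_application, generate_training


def brute_force_leverage(X, x):
    """Independent oracle: explicit inverse of X'X."""
    return float(x @ np.linalg.inv(X.T @ X) @ x)


class TestLeverage:
    def test_identity_training_matrix(self):
        m = build_leverage_model(np.eye(2))
        assert np.allclose(m.xtx_pinv, np.eye(2))
        assert leverage(m, [1.0, 0.0]) == pytest.approx(1.0)
        assert leverage(m, [0.0, 0.0]) == 0.0

    def test_matches_explicit_inverse_oracle(self, rng):
        X = rng.normal(size=(6, 3))
        m = build_leverage_model(X)
        for _ in range(5):
            x = rng.normal(size=3)
            assert leverage(m, x) == pytest.approx(brute_force_leverage(X, x), abs=1e-10)

    def test_training_leverages_sum_to_rank(self, rng):
        X = rng.normal(size=(12, 4))
        m = build_leverage_model(X)
        assert leverages(m, X).sum() == pytest.approx(m.rank, abs=1e-8)
        assert m.rank == 4

    def test_full_rank_training_rows_in_unit_interval(self, rng):
        X = rng.normal(size=(9, 3))
        h = leverages(build_leverage_model(X), X)
        assert np.all(h >= 0) and np.all(h <= 1 + 1e-12)

    def test_rank_deficient_duplicate_column(self, rng):
        base = rng.normal(size=(8, 2))
        X = np.column_stack([base, base[:, 0]])  # duplicated column
        m = build_leverage_model(X)
        assert m.rank_deficient
        h = leverages(m, X)
        assert np.all(np.isfinite(h))
        assert h.sum() == pytest.approx(m.rank, abs=1e-8)

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(10, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        x = rng.normal(size=3)
        h1 = leverage(build_leverage_model(X), x)
        h2 = leverage(build_leverage_model(X @ Q), x @ Q)
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_duplicate_training_row_never_increases_leverage(self, rng):
        X = rng.normal(size=(10, 3))
        X2 = np.vstack([X, X[0]])
        q = rng.normal(size=(20, 3))
        h1 = leverages(build_leverage_model(X), q)
        h2 = leverages(build_leverage_model(X2), q)
        assert np.all(h2 <= h1 + 1e-12)

    def test_default_threshold_three_p_over_n(self, rng):
        m = build_leverage_model(rng.normal(size=(10, 2)))
        assert m.threshold == pytest.approx(0.6)
        m2 = build_leverage_model(rng.normal(size=(4, 3)))
        assert m2.threshold == 1.0  # 3p/n capped at 1

    def test_dimension_mismatch_rejected(self, rng):
        m = build_leverage_model(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            leverage(m, [1.0, 2.0])


class TestADAssess:
    def test_training_rows_mean_leverage_is_rank_over_n(self, ad5):
        m = build_leverage_model(ad5.train, "full")
        rep = ad_assess(m, ad5.train)
        assert rep.table["leverage"].mean() == pytest.approx(m.rank / m.n)

    def test_duplicated_training_row_is_in_domain(self, ad5):
        m = build_leverage_model(ad5.train, "full")  # threshold 3*4/8 capped at 1
        rep = ad_assess(m, ad5.train.iloc[[0]])
        assert bool(rep.table["in_domain"].iloc[0])

    def test_far_queries_flagged_out(self, ad5):
        m = build_leverage_model(ad5.train, "full")
        rep = ad_assess(m, ad5.query)
        assert not rep.table.loc["q4", "in_domain"]
        assert not rep.table.loc["q5", "in_domain"]

    def test_missing_columns_rejected(self, ad5):
        m = build_leverage_model(ad5.train, "full")
        with pytest.raises(KeyError):
            ad_assess(m, ad5.query[["d1", "d2"]])

    def test_shifted_synthetic_chemicals_mostly_out(self):
        out_fracs = []
        for seed in range(5):
            cfg = GeneratorConfig(n_chemicals=150, n_descriptors=30, n_latent=16,
                                  seed=seed)
            train = generate_training(cfg)
            app = generate_application(cfg, shift_sd=10.0)
            m = build_leverage_model(train.table.data, "full")
            rep = ad_assess(m, app.table)
            shifted = rep.table.loc[app.shifted_ids, "in_domain"]
            out_fracs.append(1.0 - shifted.mean())
        assert np.mean(out_fracs) >= 0.9


class TestADCompare:
    def test_identical_subsets_agree_fully(self, ad5):
        m1 = build_leverage_model(ad5.train, "a")
        m2 = build_leverage_model(ad5.train, "b")
        cmp = ad_compare([ad_assess(m1, ad5.query), ad_assess(m2, ad5.query)])
        assert cmp["counts"]["a"] == cmp["counts"]["b"]
        assert float(cmp["agreement"].loc["a", "b"]) == 1.0

    def test_counts_sum_to_dataset_size(self, ad5):
        reports = [ad_assess(build_leverage_model(ad5.train[c], name), ad5.query[c])
                   for name, c in ad5.subsets.items()]
        cmp = ad_compare(reports)
        for counts in cmp["counts"].values():
            assert counts["in"] + counts["out"] == len(ad5.query)

    def test_overlap_matrix_matches_hand_enumeration(self, ad5):
        reports, flags = [], {}
        for name, cols in ad5.subsets.items():
            Xt = ad5.train[cols].to_numpy()
            thr = min(3 * len(cols) / len(Xt), 1.0)
            # hand/oracle flags via the explicit inverse
            flags[name] = np.array([
                brute_force_leverage(Xt, q) <= thr
                for q in ad5.query[cols].to_numpy()])
            reports.append(ad_assess(build_leverage_model(ad5.train[cols], name),
                                     ad5.query[cols]))
        cmp = ad_compare(reports)
        for a in ad5.subsets:
            for b in ad5.subsets:
                assert float(cmp["agreement"].loc[a, b]) == pytest.approx(
                    np.mean(flags[a] == flags[b]))

    def test_mismatched_chemicals_rejected(self, ad5):
        m = build_leverage_model(ad5.train, "a")
        r1 = ad_assess(m, ad5.query)
        r2 = ad_assess(m, ad5.query.iloc[:3])
        r2.subset_name = "b"
        with pytest.raises(ValueError):
            ad_compare([r1, r2])
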
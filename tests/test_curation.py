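import numpy as np
import pandas as pd
import pytest

from toxprio.curation import (CurationParams, DescriptorTable, apply_scaling,
                              curate, fit_scaling, load_descriptor_table,
                              pca_scores, ratio_filter, replicate_stability,
                              variance_filter)
from toxprio.errors import CurationError, DuplicateIdentifierError, TableMismatchError


def _table(values, ids=None, columns=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    columns = columns or [f"D{j}" for j in range(values.shape[1])]
    return DescriptorTable(pd.DataFrame(values, index=ids, columns=columns))


class TestLoadDescriptorTable:
    def test_reads_csv_with_dimensions(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,A,B,C,D\nx,1,2,3,4\ny,5,6,7,8\nz,9,10,11,12\n")
        t = load_descriptor_table(p, id_column="id")
        assert (t.n_chemicals, t.n_descriptors) == (3, 4)
        assert t.descriptor_names == ["A", "B", "C", "D"]
        assert t.ids == ["x", "y", "z"]

    def test_duplicate_identifier_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,A\nx,1\nx,2\n")
        with pytest.raises(DuplicateIdentifierError, match="duplicate identifier"):
            load_descriptor_table(p, id_column="id")

    def test_non_numeric_cell_becomes_missing(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,A,B\nx,NA,2\ny,3,4\n")
        t = load_descriptor_table(p, id_column="id")
        assert t.n_missing == 1
        assert np.isnan(t.data.loc["x", "A"])

    def test_missing_file_and_missing_id_column(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_descriptor_table(tmp_path / "absent.csv")
        p = tmp_path / "t.csv"
        p.write_text("name,A\nx,1\n")
        with pytest.raises(KeyError, match="id"):
            load_descriptor_table(p, id_column="id")


class TestReplicateStability:
    def test_identical_replicates_are_stable(self):
        t = _table([[1.0, 2.0], [3.0, 4.0]])
        assert replicate_stability([t, t, t]) == set()

    def test_large_deviation_flags_descriptor(self):
        a = _table([[1.0, 2.0], [3.0, 4.0]])
        b = _table([[1.5, 2.0], [3.0, 4.0]])  # D0 differs by 50% for one chemical
        assert replicate_stability([a, b, a], rel_tol=1e-6) == {"D0"}

    def test_tiny_deviation_is_stable(self):
        a = _table([[1.0, 2.0]], ids=["c"])
        b = _table([[1.0 + 1e-9, 2.0]], ids=["c"])
        assert replicate_stability([a, b, a], rel_tol=1e-6) == set()

    def test_mismatched_tables_rejected(self):
        a = _table([[1.0, 2.0]], ids=["c1"])
        b = _table([[1.0, 2.0]], ids=["c2"])
        with pytest.raises(TableMismatchError):
            replicate_stability([a, b, a])


class TestScaling:
    def test_factor_is_max_absolute_value(self):
        f = fit_scaling(_table([[5.0, -4.0], [10.0, 2.0]]))
        assert f["D0"] == 10.0
        assert f["D1"] == 4.0  # negative values scale by |min|

    def test_zero_column_gets_zero_factor(self):
        f = fit_scaling(_table([[0.0], [0.0]]))
        assert f["D0"] == 0.0

    def test_apply_divides_and_permits_values_above_one(self):
        t = _table([[5.0], [150.0]])
        s = apply_scaling(t, {"D0": 10.0})
        assert list(s.data["D0"]) == [0.5, 15.0]

    def test_missing_cell_stays_missing(self):
        t = _table([[np.nan], [5.0]])
        s = apply_scaling(t, {"D0": 10.0})
        assert np.isnan(s.data.iloc[0, 0]) and s.data.iloc[1, 0] == 0.5

    def test_zero_factor_for_retained_column_rejected(self):
        with pytest.raises(CurationError, match="zero scaling factor"):
            apply_scaling(_table([[1.0]]), {"D0": 0.0})

    def test_scale_descale_roundtrip(self, rng):
        t = _table(rng.normal(scale=7, size=(6, 4)))
        f = fit_scaling(t)
        back = apply_scaling(t, f).data * f
        pd.testing.assert_frame_equal(back, t.data)


class TestVarianceFilter:
    def test_constant_column_kept(self):
        assert variance_filter(_table([[1.0], [1.0]])) == ["D0"]

    def test_alternating_column_removed(self):
        # scaled column (0, 1, 0, 1): sample variance 1/3 >= 0.1
        t = _table([[0.0], [1.0], [0.0], [1.0]])
        assert np.isclose(t.data["D0"].var(ddof=1), 1 / 3)
        assert variance_filter(t) == []

    def test_exact_threshold_removed(self):
        # two values 0 and 1: sample variance exactly 0.5 -> strict < drops it
        t = _table([[0.0], [1.0]])
        assert t.data["D0"].var(ddof=1) == 0.5
        assert variance_filter(t, threshold=0.5) == []

    def test_direction_switch(self):
        t = _table([[0.0], [1.0], [0.0], [1.0]])
        assert variance_filter(t, direction="keep_above") == ["D0"]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            variance_filter(_table([[1.0]]))


class TestRatioFilter:
    @pytest.mark.parametrize("app_max,expected", [(150.0, {"D0"}), (99.0, set())])
    def test_threshold(self, app_max, expected):
        app = _table([[app_max], [1.0]])
        assert ratio_filter({"D0": 1.0}, app) == expected

    def test_zero_training_factor_with_nonzero_application(self):
        assert ratio_filter({"D0": 0.0}, _table([[3.0]])) == {"D0"}
        assert ratio_filter({"D0": 0.0}, _table([[0.0]])) == set()


class TestCurate:
    def test_fixture_partition(self, curation6):
        train, app, report = curate(curation6.replicates, curation6.application)
        assert report.kept == curation6.expected_kept
        assert report.removed_unstable_replicate == curation6.expected_unstable
        assert report.removed_variance == curation6.expected_variance
        assert report.removed_ratio == curation6.expected_ratio
        # bookkeeping: kept + removals partition the original descriptors
        assert report.n_original() == 6
        all_sets = [set(report.kept), *report.removal_sets.values()]
        union = set().union(*all_sets)
        assert union == set(curation6.replicates[0].descriptor_names)
        assert sum(len(s) for s in all_sets) == len(union)  # pairwise disjoint

    def test_curated_tables_share_columns(self, curation6):
        train, app, _ = curate(curation6.replicates, curation6.application)
        assert train.descriptor_names == app.descriptor_names

    def test_all_clean_columns_kept(self):
        t = _table(np.array([[9.0, 9.5], [10.0, 10.0], [9.2, 9.8]]))
        app = _table(np.array([[8.0, 9.0]]), ids=["a1"])
        _, _, report = curate([t, t, t], app)
        assert report.kept == ["D0", "D1"]

    def test_idempotent(self, curation6):
        train, app, _ = curate(curation6.replicates, curation6.application)
        train2, app2, report2 = curate([train, train, train], app)
        pd.testing.assert_frame_equal(train2.data, train.data)
        pd.testing.assert_frame_equal(app2.data, app.data)
        assert report2.kept == train.descriptor_names

    def test_scaling_factors_cover_kept(self, curation6):
        _, _, report = curate(curation6.replicates, curation6.application)
        assert set(report.scaling_factors) == set(report.kept)


class TestPCA:
    def test_collinear_data_one_component(self):
        x = np.arange(10.0)
        scores, evr = pca_scores(np.column_stack([x, 2 * x]), n_components=2)
        assert evr[0] == pytest.approx(1.0)
        assert evr[1] == pytest.approx(0.0, abs=1e-12)

    def test_scores_centered_and_variance_sorted(self, rng):
        scores, evr = pca_scores(rng.normal(size=(20, 5)), n_components=3)
        assert np.allclose(scores.mean(axis=0), 0, atol=1e-10)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(5, 4))
        scores, evr = pca_scores(X, n_components=2)
        # independent oracle: eigendecomposition of the covariance matrix
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(np.cov(Xc, rowvar=False))
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        expected = Xc @ V[:, :2]
        for j in range(2):
            assert (np.allclose(scores[:, j], expected[:, j], atol=1e-8)
                    or np.allclose(scores[:, j], -expected[:, j], atol=1e-8))
        assert np.allclose(evr[:2], (w / w.sum())[:2])

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_scores(rng.normal(size=(3, 2)), n_components=3)
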
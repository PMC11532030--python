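import numpy as np
import pytest

from kcatpred import (
    KcatDataset,
    KcatRecord,
    clean_dataset,
    fit_apply_zscore,
    inverse_transform_targets,
    split_dataset,
    transform_targets,
)
from kcatpred.errors import DataError, ParameterError, ShapeError


def _rec(i, kcat, seq="MKVLAYTTRE", rxn="CCO>>CC=O", split=None):
    return KcatRecord(
        record_id=f"r{i}", sequence=seq, reaction=rxn, kcat=kcat, split_label=split
    )


class TestCleanDataset:
    def test_clean_input_passes_through(self):
        ds = KcatDataset([_rec(i, float(i + 1), rxn=f"{'C' * (i + 1)}>>O") for i in range(5)])
        out, report = clean_dataset(ds)
        assert len(out) == 5
        assert (
            report.n_missing_removed
            == report.n_duplicates_merged
            == report.n_outliers_removed
            == 0
        )

    def test_duplicates_merge_to_geometric_mean(self):
        ds = KcatDataset(
            [_rec(0, 1.0), _rec(1, 100.0), _rec(2, 5.0, rxn="CC>>C.C")]
        )
        out, report = clean_dataset(ds)
        merged = {r.record_id: r.kcat for r in out}
        assert merged["r0"] == pytest.approx(10.0)
        assert report.n_duplicates_merged == 1 and report.n_output == 2

    def test_single_extreme_outlier_removed_at_z3(self):
        rng = np.random.default_rng(0)
        records = [
            _rec(i, float(10 ** rng.normal(0, 0.1)), rxn=f"{'C' * (i + 1)}>>O")
            for i in range(50)
        ]
        records.append(_rec(99, 1e9, rxn="N>>O"))
        out, report = clean_dataset(KcatDataset(records), outlier_z=3.0)
        assert report.n_outliers_removed == 1
        assert "r99" not in {r.record_id for r in out}

    def test_missing_kcat_removed_and_counted(self):
        ds = KcatDataset([_rec(0, 2.0), _rec(1, None, rxn="CC>>C.C")])
        out, report = clean_dataset(ds)
        assert report.n_missing_removed == 1 and len(out) == 1

    def test_report_counts_always_reconcile(self):
        ds = KcatDataset(
            [_rec(0, 1.0), _rec(1, 100.0), _rec(2, None, rxn="CC>>C.C"), _rec(3, 2.0, rxn="N>>O")]
        )
        _, report = clean_dataset(ds)
        assert report.n_output == (
            report.n_input
            - report.n_missing_removed
            - report.n_duplicates_merged
            - report.n_outliers_removed
        )

    def test_all_removed_warns(self):
        ds = KcatDataset([_rec(0, None)])
        with pytest.warns(UserWarning, match="every record"):
            clean_dataset(ds)


class TestTransformTargets:
    @pytest.mark.parametrize("kcat,expected", [(1.0, 0.0), (1000.0, 3.0)])
    def test_log10_values(self, kcat, expected):
        ds = KcatDataset([_rec(0, kcat)])
        assert transform_targets(ds)[0] == pytest.approx(expected)

    def test_inverse_roundtrip(self):
        x = np.array([0.007])
        assert inverse_transform_targets(np.log10(x))[0] == pytest.approx(
            0.007, abs=1e-12
        )

    def test_missing_kcat_names_record(self):
        ds = KcatDataset([_rec(0, None)])
        with pytest.raises(DataError, match="r0"):
            transform_targets(ds)


class TestZscore:
    def test_hand_computed_column(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Z, _, params = fit_apply_zscore(X)
        assert np.allclose(Z[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert params.sds[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 3))
        X = (X - X.mean(0)) / X.std(0)
        Z, _, _ = fit_apply_zscore(X)
        assert np.abs(Z - X).max() < 1e-9

    def test_constant_column_maps_to_zero(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        Z, _, params = fit_apply_zscore(X)
        assert (Z[:, 0] == 0).all() and params.sds[0] == 0.0

    def test_test_matrix_uses_train_params_only(self):
        rng = np.random.default_rng(2)
        Xtr = rng.standard_normal((100, 4)) * 3 + 1
        Xte = rng.standard_normal((40, 4)) * 10 - 5
        Ztr, Zte, params = fit_apply_zscore(Xtr, Xte)
        assert params.fitted_on == "train"
        assert np.allclose(Zte, (Xte - Xtr.mean(0)) / Xtr.std(0))
        # train columns exactly standardized
        assert np.abs(Ztr.mean(0)).max() < 1e-9
        assert np.abs(Ztr.std(0) - 1).max() < 1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            fit_apply_zscore(np.zeros((5, 3)), np.zeros((5, 4)))


class TestSplitDataset:
    def test_sizes_disjoint_exhaustive(self):
        ds = KcatDataset([_rec(i, 1.0, rxn=f"{'C' * (i + 1)}>>O") for i in range(10)])
        train, test = split_dataset(ds, test_frac=0.2, seed=0)
        assert len(train) == 8 and len(test) == 2
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(ds.record_ids)

    def test_same_seed_identical_partition(self):
        ds = KcatDataset([_rec(i, 1.0, rxn=f"{'C' * (i + 1)}>>O") for i in range(30)])
        assert split_dataset(ds, 0.3, seed=4) == split_dataset(ds, 0.3, seed=4)

    def test_explicit_labels_take_precedence(self):
        ds = KcatDataset(
            [
                _rec(0, 1.0, split="train"),
                _rec(1, 1.0, rxn="CC>>C.C", split="test"),
                _rec(2, 1.0, rxn="N>>O", split="train"),
            ]
        )
        train, test = split_dataset(ds)
        assert train == ["r0", "r2"] and test == ["r1"]

    def test_labels_plus_fraction_is_usage_error(self):
        ds = KcatDataset([_rec(0, 1.0, split="train"), _rec(1, 1.0, rxn="N>>O", split="test")])
        with pytest.raises(ParameterError):
            split_dataset(ds, test_frac=0.5, seed=1)

    def test_bad_fraction_rejected(self):
        ds = KcatDataset([_rec(i, 1.0, rxn=f"{'C' * (i + 1)}>>O") for i in range(4)])
        with pytest.raises(ParameterError):
            split_dataset(ds, test_frac=1.5, seed=0)
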
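"""Classification tests: splitting, SVM, fusion strategies, report math."""

import numpy as np
import pytest

from plvsleep.bands import BAND_ORDER, STAGE_ORDER
from plvsleep.classification import (
    FeatureTable,
    SplitSpec,
    band_feature_tables,
    classify,
    decision_level_stacking,
    evaluate,
    feature_level_fusion,
    hybrid_fusion,
    run_experiment_grid,
    split_train_test,
    train_classifier,
)

from conftest import synthetic_feature_frame


def cluster_tables(rng, n_per_stage=20, informative_bands=None, spread=0.05):
    """Per-band FeatureTables with Gaussian class clusters.

    ``informative_bands`` maps band -> dict stage -> mean shift; bands not
    listed carry no class information.
    """
    informative_bands = informative_bands or {}
    labels = np.repeat(STAGE_ORDER, n_per_stage)
    tables = {}
    for band in BAND_ORDER:
        x = 0.5 + spread * rng.standard_normal((len(labels), 66))
        shifts = informative_bands.get(band, {})
        for k, stage in enumerate(labels):
            x[k] += shifts.get(stage, 0.0)
        tables[band] = FeatureTable(
            matrix=x,
            column_provenance=tuple((band, f"f{i}") for i in range(66)),
            labels=labels.copy(),
        )
    return tables


class TestSplitTrainTest:
    def test_75_25_arithmetic(self):
        labels = np.repeat(STAGE_ORDER, 100)
        split = split_train_test(labels, seed=0)
        assert len(split.train_indices) == 225
        assert len(split.test_indices) == 75

    def test_same_seed_same_split(self):
        labels = np.repeat(STAGE_ORDER, 20)
        a = split_train_test(labels, seed=3)
        b = split_train_test(labels, seed=3)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            counts = rng.integers(8, 40, size=3)
            labels = np.concatenate([
                np.repeat(stage, c) for stage, c in zip(STAGE_ORDER, counts)])
            split = split_train_test(labels, seed=int(rng.integers(1000)))
            for stage, c in zip(STAGE_ORDER, counts):
                got = (labels[split.train_indices] == stage).sum()
                assert abs(got - 0.75 * c) <= 1.0

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(np.array([0, 1]), np.array([1, 2]), 0.75, 0)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(["REM", "REM", "N2", "N2", "N2", "N2"], seed=0)


class TestTrainAndEvaluate:
    def test_separable_clusters_reach_full_accuracy(self):
        rng = np.random.default_rng(1)
        tables = cluster_tables(rng, informative_bands={
            "alpha": {"REM": 0.0, "N2": 1.0, "N3": 2.0}})
        split = split_train_test(tables["alpha"].labels, seed=0)
        report = classify(tables["alpha"], split)
        assert report.accuracy == 100.0

    def test_permuted_labels_sit_at_chance_over_seeds(self):
        rng = np.random.default_rng(2)
        accs = []
        for seed in range(20):
            tables = cluster_tables(rng, n_per_stage=20)  # no class information
            split = split_train_test(tables["alpha"].labels, seed=seed)
            accs.append(classify(tables["alpha"], split).accuracy)
        n_test = 15 * 20
        se = 100 * np.sqrt((1 / 3) * (2 / 3) / n_test)
        assert abs(np.mean(accs) - 100 / 3) < 3 * se

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(3)
        tables = cluster_tables(rng, informative_bands={"delta": {"N3": 0.3}})
        split = split_train_test(tables["delta"].labels, seed=1)
        m1 = train_classifier(tables["delta"].matrix[split.train_indices],
                              tables["delta"].labels[split.train_indices])
        m2 = train_classifier(tables["delta"].matrix[split.train_indices],
                              tables["delta"].labels[split.train_indices])
        x_test = tables["delta"].matrix[split.test_indices]
        np.testing.assert_array_equal(m1.predict(x_test), m2.predict(x_test))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((5, 3)), ["N2"] * 5)

    def test_confusion_arithmetic(self):
        truth = ["REM"] * 10 + ["N2"] * 10 + ["N3"] * 10
        preds = ["REM"] * 8 + ["N2"] * 2 + ["N2"] * 10 + ["N3"] * 10
        report = evaluate(preds, truth)
        assert report.accuracy == pytest.approx(93.3333, abs=1e-3)
        assert report.per_class_tpr == {"REM": 80.0, "N2": 100.0, "N3": 100.0}
        np.testing.assert_array_equal(
            report.confusion, [[8, 2, 0], [0, 10, 0], [0, 0, 10]])
        # invariants: rows sum to class counts, accuracy = trace/total
        assert report.confusion.sum() == 30
        assert report.accuracy == pytest.approx(
            100 * np.trace(report.confusion) / report.confusion.sum())

    def test_all_correct(self):
        report = evaluate(["REM", "N2"], ["REM", "N2"])
        assert report.accuracy == 100.0
        assert all(v == 100.0 for v in report.per_class_tpr.values())

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])


class TestFeatureLevelFusion:
    def test_column_counts(self):
        rng = np.random.default_rng(4)
        tables = cluster_tables(rng, n_per_stage=4)
        assert feature_level_fusion(tables, ("delta", "beta1")).matrix.shape[1] == 132
        assert feature_level_fusion(tables).matrix.shape[1] == 396

    def test_single_band_is_identity(self):
        rng = np.random.default_rng(5)
        tables = cluster_tables(rng, n_per_stage=4)
        fused = feature_level_fusion(tables, ("alpha",))
        np.testing.assert_array_equal(fused.matrix, tables["alpha"].matrix)

    def test_canonical_band_order_in_provenance(self):
        rng = np.random.default_rng(6)
        tables = cluster_tables(rng, n_per_stage=4)
        fused = feature_level_fusion(tables)
        assert fused.bands == tuple(BAND_ORDER)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        tables = cluster_tables(rng, n_per_stage=4)
        bad = FeatureTable(tables["delta"].matrix,
                           tables["delta"].column_provenance,
                           tables["delta"].labels[::-1].copy())
        with pytest.raises(ValueError):
            feature_level_fusion({"delta": bad, "theta": tables["theta"]},
                                 ("delta", "theta"))


class TestStackingAndHybrid:
    def test_perfect_base_classifiers_give_perfect_stack(self):
        rng = np.random.default_rng(8)
        shifts = {"REM": 0.0, "N2": 1.0, "N3": 2.0}
        tables = cluster_tables(rng, informative_bands={
            b: shifts for b in ("delta", "alpha")})
        split = split_train_test(tables["delta"].labels, seed=2)
        report = decision_level_stacking(tables, split, ("delta", "alpha"))
        assert report.accuracy == 100.0
        assert report.strategy == "E"

    def test_one_informative_band_survives_noise_bands(self):
        rng = np.random.default_rng(9)
        tables = cluster_tables(rng, n_per_stage=20, informative_bands={
            "alpha": {"REM": 0.0, "N2": 0.6, "N3": 1.2}})
        split = split_train_test(tables["alpha"].labels, seed=3)
        single = classify(tables["alpha"], split).accuracy
        stacked = decision_level_stacking(tables, split).accuracy
        assert stacked >= single - 3.0

    def test_single_band_stacking_rejected(self):
        rng = np.random.default_rng(10)
        tables = cluster_tables(rng, n_per_stage=4)
        split = split_train_test(tables["delta"].labels, seed=0)
        with pytest.raises(ValueError):
            decision_level_stacking(tables, split, ("delta",))

    def test_hybrid_bookkeeping_and_strategy_label(self):
        rng = np.random.default_rng(11)
        shifts = {"REM": 0.0, "N2": 1.0, "N3": 2.0}
        tables = cluster_tables(rng, informative_bands={
            b: shifts for b in BAND_ORDER})
        split = split_train_test(tables["delta"].labels, seed=1)
        report = hybrid_fusion(tables, split)
        assert report.strategy == "E(C)"
        assert set(report.bands) == set(BAND_ORDER)
        assert report.accuracy == 100.0

    def test_empty_pair_list_rejected(self):
        rng = np.random.default_rng(12)
        tables = cluster_tables(rng, n_per_stage=4)
        split = split_train_test(tables["delta"].labels, seed=0)
        with pytest.raises(ValueError):
            hybrid_fusion(tables, split, band_pairs=[])


class TestExperimentGrid:
    def test_single_strategy_single_subset(self):
        rng = np.random.default_rng(13)
        tables = cluster_tables(rng, n_per_stage=8)
        grid = run_experiment_grid(tables, strategies=("C",),
                                   band_subsets=(("delta", "theta"),),
                                   include_single_bands=False, seed=0)
        assert len(grid) == 1
        assert grid.iloc[0]["strategy"] == "C"

    def test_grid_rows_satisfy_report_invariants(self, default_features):
        tables = band_feature_tables(default_features)
        grid = run_experiment_grid(tables, seed=4)
        assert {"single", "C", "E", "E(C)"} <= set(grid["strategy"])
        assert grid["accuracy"].between(0, 100).all()
        for col in ("tpr_REM", "tpr_N2", "tpr_N3"):
            assert grid[col].between(0, 100).all()

    def test_grid_is_deterministic(self):
        rng = np.random.default_rng(14)
        tables = cluster_tables(rng, n_per_stage=8)
        a = run_experiment_grid(tables, strategies=("C", "E"),
                                band_subsets=(("delta", "theta"),), seed=5)
        rng = np.random.default_rng(14)
        tables = cluster_tables(rng, n_per_stage=8)
        b = run_experiment_grid(tables, strategies=("C", "E"),
                                band_subsets=(("delta", "theta"),), seed=5)
        assert a.equals(b)

    def test_unknown_strategy_rejected(self):
        rng = np.random.default_rng(15)
        tables = cluster_tables(rng, n_per_stage=8)
        with pytest.raises(ValueError, match="unknown strategies"):
            run_experiment_grid(tables, strategies=("bagging",))


class TestBandFeatureTables:
    def test_long_frame_split_preserves_labels_and_provenance(self):
        rng = np.random.default_rng(16)
        features = synthetic_feature_frame(rng, n_per_stage=5)
        tables = band_feature_tables(features)
        assert set(tables) == set(BAND_ORDER)
        for band, table in tables.items():
            assert table.matrix.shape == (15, 66)
            assert table.bands == (band,)

    def test_no_leakage_between_split_parts(self, default_features):
        tables = band_feature_tables(default_features)
        split = split_train_test(tables["alpha"].labels, seed=0)
        train = set(split.train_indices.tolist())
        test = set(split.test_indices.tolist())
        assert not train & test
        assert train | test == set(range(len(tables["alpha"].labels)))
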
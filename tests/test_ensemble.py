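"""Spatial blocks, partitioning, classifier contract, ensemble aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdmpipe import (
    GridGeometry,
    OccurrenceSet,
    PredictorStack,
    aggregate_importance,
    build_blocks,
    extract_training_table,
    fit_classifier,
    majority_vote,
    partition_blocks,
    predict_surface,
    subset_predictors,
)
from sdmpipe.metrics import auc_roc
from conftest import make_grid


class TestBlocks:
    @pytest.mark.parametrize(
        "shape,size,expected",
        [((20, 20), 10, 4), ((25, 25), 10, 9), ((6, 6), 1, 36)],
    )
    def test_block_counts(self, shape, size, expected):
        layout = build_blocks(GridGeometry(shape[0], shape[1], 30.0), size)
        assert layout.n_blocks == expected
        assert len(np.unique(layout.block_id)) == expected

    def test_blocks_are_contiguous_squares(self):
        layout = build_blocks(GridGeometry(20, 20, 30.0), 10)
        assert (layout.block_id[:10, :10] == 0).all()
        assert (layout.block_id[10:, 10:] == 3).all()


class TestPartition:
    def test_seventy_thirty_split_of_ten_blocks(self):
        layout = build_blocks(GridGeometry(20, 50, 30.0), 10)
        occupied = set(range(10))
        part = partition_blocks(layout, occupied, 0.7, seed=0)
        counts = pd.Series(part).value_counts()
        assert counts["train"] == 7 and counts["validation"] == 3

    def test_same_seed_same_partition(self):
        layout = build_blocks(GridGeometry(20, 50, 30.0), 10)
        a = partition_blocks(layout, set(range(10)), 0.7, seed=5)
        b = partition_blocks(layout, set(range(10)), 0.7, seed=5)
        assert a == b

    def test_train_frequency_close_to_fraction(self):
        layout = build_blocks(GridGeometry(20, 50, 30.0), 10)
        occupied = set(range(10))
        freq = np.zeros(10)
        n_seeds = 1000
        for seed in range(n_seeds):
            part = partition_blocks(layout, occupied, 0.7, seed=seed)
            for b in occupied:
                freq[b] += part[b] == "train"
        assert np.abs(freq / n_seeds - 0.7).max() <= 0.05

    def test_presences_in_both_partitions(self):
        layout = build_blocks(GridGeometry(20, 50, 30.0), 10)
        presence_blocks = {0, 1}
        for seed in range(50):
            part = partition_blocks(
                layout, set(range(10)), 0.7, seed=seed, presence_blocks=presence_blocks
            )
            sides = {part[b] for b in presence_blocks}
            assert sides == {"train", "validation"}

    def test_single_block_impossible(self):
        layout = build_blocks(GridGeometry(10, 10, 30.0), 10)
        with pytest.raises(ValueError):
            partition_blocks(layout, {0}, 0.7, seed=0)


class TestTrainingTable:
    def _stack(self, seed=0, shape=(10, 10)):
        rng = np.random.default_rng(seed)
        return PredictorStack(
            {f"b{i}": make_grid(rng.normal(size=shape)) for i in range(4)}
        )

    def test_rows_labels_and_feature_lookup(self):
        stack = self._stack()
        geom = stack.geometry
        layout = build_blocks(geom, 5)
        rng = np.random.default_rng(1)
        pres = OccurrenceSet(np.column_stack([rng.uniform(0, 299, 5), rng.uniform(-299, 0, 5)]))
        pa = OccurrenceSet(np.column_stack([rng.uniform(0, 299, 5), rng.uniform(-299, 0, 5)]))
        partition = {b: "train" for b in range(layout.n_blocks)}
        table = extract_training_table(stack, pres, pa, layout, partition)
        assert len(table) == 10
        assert table["label"].sum() == 5
        for _, row in table.sample(5, random_state=0).iterrows():
            r, c = int(row["row"]), int(row["col"])
            for name in stack.band_names:
                assert row[name] == stack[name].values[r, c]

    def test_point_on_masked_cell_dropped(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        stack = PredictorStack({"b": make_grid(np.ones((10, 10)), mask=mask)})
        layout = build_blocks(stack.geometry, 5)
        pres = OccurrenceSet([[15.0, -15.0], [45.0, -45.0]])  # first point on masked cell
        pa = OccurrenceSet([[75.0, -75.0]])
        with pytest.warns(UserWarning, match="masked"):
            table = extract_training_table(
                stack, pres, pa, layout, {b: "train" for b in range(4)}
            )
        assert len(table) == 2


class TestClassifier:
    def _separable_table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        x = np.r_[rng.normal(-2, 0.5, n // 2), rng.normal(2, 0.5, n // 2)]
        return pd.DataFrame(
            {"f1": x, "f2": rng.normal(size=n), "label": np.r_[np.zeros(n // 2), np.ones(n // 2)]}
        )

    def test_separable_data_perfect_training_accuracy(self):
        table = self._separable_table()
        model = fit_classifier(table, n_trees=50, seed=0, feature_names=["f1", "f2"])
        pred = model.predict_probability(table[["f1", "f2"]].to_numpy()) >= 0.5
        assert (pred == table["label"].to_numpy().astype(bool)).all()

    def test_same_seed_identical_predictions(self):
        table = self._separable_table(seed=3)
        X = table[["f1", "f2"]].to_numpy()
        a = fit_classifier(table, n_trees=50, seed=9, feature_names=["f1", "f2"])
        b = fit_classifier(table, n_trees=50, seed=9, feature_names=["f1", "f2"])
        assert np.array_equal(a.predict_probability(X), b.predict_probability(X))

    def test_single_class_rejected(self):
        table = self._separable_table()
        table["label"] = 1
        with pytest.raises(ValueError, match="single class"):
            fit_classifier(table, n_trees=10, feature_names=["f1", "f2"])

    def test_noise_labels_give_chance_level_auc(self):
        rng = np.random.default_rng(5)
        aucs = []
        for rep in range(50):
            X = rng.normal(size=(200, 5))
            y = rng.integers(0, 2, 200)
            train = pd.DataFrame(X[:100], columns=[f"f{i}" for i in range(5)])
            train["label"] = y[:100]
            if train["label"].nunique() < 2:
                continue
            model = fit_classifier(train, n_trees=50, seed=rep,
                                   feature_names=[f"f{i}" for i in range(5)])
            scores = model.predict_probability(X[100:])
            aucs.append(auc_roc(scores, y[100:]))
        assert 0.45 <= np.mean(aucs) <= 0.55
        assert all(0.3 <= a <= 0.7 for a in aucs)


class TestPredictSurface:
    def test_binary_is_thresholded_probability(self, small_ensemble):
        for prob, binary in zip(small_ensemble.probability_grids, small_ensemble.binary_grids):
            valid = prob.valid
            assert np.array_equal(binary.values[valid], (prob.values[valid] >= 0.5).astype(float))

    def test_masked_cells_propagate(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 2] = True
        stack = PredictorStack({"f1": make_grid(np.random.default_rng(0).normal(size=(6, 6)), mask=mask)})

        class ConstantModel:
            feature_names = ["f1"]

            def predict_probability(self, X):
                return np.full(len(X), 0.25)

        prob, binary = predict_surface(ConstantModel(), stack)
        assert prob.nodata_mask[2, 2] and binary.nodata_mask[2, 2]
        assert (prob.values[prob.valid] == 0.25).all()
        assert (binary.values[binary.valid] == 0.0).all()

    def test_band_mismatch_raises(self):
        stack = PredictorStack({"other": make_grid(np.ones((3, 3)))})

        class M:
            feature_names = ["f1"]

        with pytest.raises(KeyError):
            predict_surface(M(), stack)


class TestMajorityVote:
    def test_six_of_ten_is_presence(self):
        grids = [make_grid([[1.0]]) for _ in range(6)] + [make_grid([[0.0]]) for _ in range(4)]
        assert majority_vote(grids).values[0, 0] == 1.0

    def test_five_five_tie_is_absence(self):
        grids = [make_grid([[1.0]]) for _ in range(5)] + [make_grid([[0.0]]) for _ in range(5)]
        assert majority_vote(grids).values[0, 0] == 0.0

    def test_matches_bruteforce_counting(self):
        rng = np.random.default_rng(7)
        grids = [make_grid(rng.integers(0, 2, (6, 6)).astype(float)) for _ in range(10)]
        out = majority_vote(grids)
        for r in range(6):
            for c in range(6):
                votes = [g.values[r, c] for g in grids]
                assert out.values[r, c] == float(sum(votes) > len(votes) / 2)

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestImportance:
    def test_normalization_example(self):
        out = aggregate_importance([[2.0, 1.0, 1.0]])
        assert list(out.values()) == pytest.approx([50.0, 25.0, 25.0])

    def test_identical_vectors_mean_equals_each(self):
        vecs = [{"a": 3.0, "b": 1.0}] * 4
        out = aggregate_importance(vecs)
        assert out == {"a": 75.0, "b": 25.0}

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.lists(st.floats(0.001, 100.0), min_size=4, max_size=4),
            min_size=1,
            max_size=8,
        )
    )
    def test_output_sums_to_100(self, vecs):
        out = aggregate_importance(vecs)
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            aggregate_importance([[0.0, 0.0]])

    def test_subset_threshold(self):
        imp = {"a": 40.0, "b": 10.0, "c": 5.0, "d": 3.6, "e": 3.4, "f": 1.0}
        assert subset_predictors(imp, 3.5) == ["a", "b", "c", "d"]
        assert subset_predictors(imp, 0.0) == ["a", "b", "c", "d", "e", "f"]

    def test_subset_exactly_seven(self):
        imp = {f"p{i}": v for i, v in enumerate(
            [20.0, 15.0, 10.0, 8.0, 6.0, 5.0, 4.0, 3.4, 3.0, 2.0]
        )}
        kept = subset_predictors(imp, 3.5)
        assert len(kept) == 7

    def test_empty_subset_warns(self):
        with pytest.warns(UserWarning, match="threshold"):
            assert subset_predictors({"a": 1.0}, 3.5) == []


class TestEnsembleAggregates:
    def test_hsi_mean_within_iteration_extrema(self, small_ensemble):
        cube = np.stack([g.values for g in small_ensemble.probability_grids])
        valid = small_ensemble.hsi_mean.valid
        assert (small_ensemble.hsi_mean.values[valid] >= cube.min(axis=0)[valid] - 1e-12).all()
        assert (small_ensemble.hsi_mean.values[valid] <= cube.max(axis=0)[valid] + 1e-12).all()
        vals = small_ensemble.hsi_mean.values[valid]
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_hsi_sd_nonnegative_population(self, small_ensemble):
        cube = np.stack([g.values for g in small_ensemble.probability_grids])
        valid = small_ensemble.hsi_sd.valid
        assert np.allclose(small_ensemble.hsi_sd.values[valid], cube.std(axis=0)[valid])

    def test_mean_importance_sums_to_100(self, small_ensemble):
        assert sum(small_ensemble.mean_importance_percent.values()) == pytest.approx(
            100.0, abs=1e-6
        )

    def test_iteration_order_irrelevant(self, small_ensemble):
        from sdmpipe.ensemble import EnsembleResult

        perm = np.random.default_rng(0).permutation(len(small_ensemble.probability_grids))
        shuffled = EnsembleResult(
            [small_ensemble.probability_grids[i] for i in perm],
            [small_ensemble.binary_grids[i] for i in perm],
            [small_ensemble.importance_vectors[i] for i in perm],
            [small_ensemble.metric_sets[i] for i in perm],
        ).aggregate()
        assert np.allclose(shuffled.hsi_mean.values, small_ensemble.hsi_mean.values)
        assert np.allclose(shuffled.hsi_sd.values, small_ensemble.hsi_sd.values)
        assert np.array_equal(
            shuffled.majority_binary.values, small_ensemble.majority_binary.values
        )
        for k, v in shuffled.mean_importance_percent.items():
            assert v == pytest.approx(small_ensemble.mean_importance_percent[k])
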
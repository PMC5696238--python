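"""Decision Forest learner: splitting, tree growth, disjoint pools, persistence."""

import numpy as np
import pytest

from dfqsar import (
    BINDER,
    NON_BINDER,
    DescriptorTable,
    ForestConfig,
    LabeledDataset,
    best_split,
    build_tree,
    classify,
    load_model,
    predict_proba,
    predict_table,
    prediction_confidence,
    save_model,
    train_forest,
)
from dfqsar.forest import ForestModel, TreeNode, _tree_fractions

from conftest import oracle_best_split, oracle_grow_tree


class TestBestSplit:
    def test_pure_children_from_even_prior_gain_one_bit(self):
        thr, gain = best_split(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]), 1)
        assert thr == 2.5
        assert gain == pytest.approx(1.0)

    def test_pure_labels_give_no_split(self):
        assert best_split(np.arange(6.0), np.ones(6, dtype=int), 1) is None

    def test_min_leaf_blocks_all_candidates(self):
        # only admissible boundary sits between identical values
        assert best_split(np.array([1.0, 1.0, 2.0, 2.0]), np.array([0, 1, 0, 1]), 2) is not None
        assert best_split(np.array([1.0, 2.0]), np.array([0, 1]), 2) is None

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            best_split(np.arange(4.0), np.array([0, 1]), 1)

    def test_gain_ties_resolve_to_smallest_threshold(self):
        # symmetric pattern: splits at 1.5 and 2.5 have equal gain
        thr, _ = best_split(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]), 1)
        assert thr == 1.5

    @pytest.mark.parametrize("trial", range(200))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 41))
        values = rng.normal(size=n)
        labels = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
        min_leaf = int(rng.integers(1, 4))
        got = best_split(values, labels, min_leaf)
        expected = oracle_best_split(values, labels, min_leaf)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert got[0] == pytest.approx(expected[0], abs=1e-12)
            assert got[1] == pytest.approx(expected[1], abs=1e-9)


def _tree_to_dict(node: TreeNode):
    if node.is_leaf:
        return {"binder_fraction": node.binder_fraction, "n_train": node.n_train}
    return {
        "descriptor_name": node.descriptor_name,
        "threshold": node.threshold,
        "left": _tree_to_dict(node.left),
        "right": _tree_to_dict(node.right),
    }


def _assert_same_structure(got, want, tol=1e-9):
    if "binder_fraction" in want:
        assert got["binder_fraction"] == pytest.approx(want["binder_fraction"])
        assert got["n_train"] == want["n_train"]
        return
    assert got["descriptor_name"] == want["descriptor_name"]
    assert got["threshold"] == pytest.approx(want["threshold"], abs=tol)
    _assert_same_structure(got["left"], want["left"], tol)
    _assert_same_structure(got["right"], want["right"], tol)


class TestBuildTree:
    def test_perfect_descriptor_yields_depth_one_tree(self, separable_dataset):
        tree = build_tree(separable_dataset, ["sep"], ForestConfig(min_leaf=5))
        assert tree.descriptor_name == "sep"
        assert tree.left.is_leaf and tree.right.is_leaf
        frac = _tree_fractions(tree, separable_dataset.table)
        acc = ((frac >= 0.5).astype(int) == separable_dataset.labels).mean()
        assert acc == 1.0

    def test_single_class_dataset_returns_leaf(self, toy_table):
        ds = LabeledDataset(toy_table, np.ones(12, dtype=int))
        tree = build_tree(ds, ["d1", "d2"], ForestConfig())
        assert tree.is_leaf
        assert tree.binder_fraction == 1.0

    def test_empty_pool_is_hard_error(self, separable_dataset):
        with pytest.raises(ValueError):
            build_tree(separable_dataset, [], ForestConfig())

    def test_structure_matches_naive_reference_grower(self, random_dataset):
        config = ForestConfig(min_leaf=3)
        tree = build_tree(random_dataset, random_dataset.table.descriptor_names, config)
        want = oracle_grow_tree(
            random_dataset.table.values,
            random_dataset.labels,
            list(range(random_dataset.table.n_descriptors)),
            random_dataset.table.descriptor_names,
            min_leaf=3,
        )
        _assert_same_structure(_tree_to_dict(tree), want)

    def test_max_depth_caps_growth(self, random_dataset):
        tree = build_tree(random_dataset, random_dataset.table.descriptor_names,
                          ForestConfig(min_leaf=2, max_depth=1))
        assert tree.left.is_leaf and tree.right.is_leaf


class TestTrainForest:
    def test_trees_use_disjoint_descriptor_sets(self, sparse_data):
        dataset, _ = sparse_data
        model = train_forest(dataset, ForestConfig(max_trees=5))
        seen = set()
        for s in model.descriptor_sets:
            assert not (seen & set(s))
            seen |= set(s)

    def test_max_trees_one_reduces_to_build_tree(self, separable_dataset):
        model = train_forest(separable_dataset, ForestConfig(max_trees=1))
        solo = build_tree(separable_dataset,
                          separable_dataset.table.descriptor_names, ForestConfig())
        assert model.n_trees == 1
        _assert_same_structure(_tree_to_dict(model.trees[0]), _tree_to_dict(solo))

    def test_consensus_never_degrades_first_tree_training_score(self, benchmark_data):
        dataset, _ = benchmark_data
        model = train_forest(dataset)
        from dfqsar.forest import _balanced_accuracy, _consensus_proba
        first = _balanced_accuracy(
            dataset.labels, _tree_fractions(model.trees[0], dataset.table))
        full = _balanced_accuracy(
            dataset.labels, _consensus_proba(model.trees, dataset.table))
        assert full >= first

    def test_single_class_is_hard_error(self, toy_table):
        with pytest.raises(ValueError):
            train_forest(LabeledDataset(toy_table, np.ones(12, dtype=int)))

    def test_training_is_deterministic(self, sparse_data, tmp_path):
        dataset, _ = sparse_data
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        save_model(train_forest(dataset), a)
        save_model(train_forest(dataset), b)
        assert a.read_bytes() == b.read_bytes()

    def test_signal_recovery_on_balanced_planted_data(self):
        """With both classes well represented the forest separates planted
        signal almost perfectly out-of-sample, while the same pipeline on
        permuted labels stays at chance."""
        from dfqsar import cross_validate, generate_dataset, permutation_test, scaled_config
        cfg = scaled_config(seed=4, n_binders=250, n_nonbinders=250)
        dataset, _ = generate_dataset(cfg)
        cv = cross_validate(dataset, iterations=3, base_seed=21)
        assert cv.summary()["balanced_accuracy"]["mean"] > 0.9
        null = permutation_test(dataset, replicates=3, base_seed=22)
        assert abs(null.summary()["balanced_accuracy"]["mean"] - 0.5) < 0.05


class TestPrediction:
    def _two_leaf_model(self, fracs):
        trees = [TreeNode(binder_fraction=f, n_train=10) for f in fracs]
        return ForestModel(trees, [[] for _ in fracs], ForestConfig(), ["d1"])

    def test_consensus_is_unweighted_mean(self):
        model = self._two_leaf_model([1.0, 0.5])
        assert predict_proba(model, {"d1": 0.0}) == 0.75

    def test_single_tree_leaf_fraction_passes_through(self):
        model = self._two_leaf_model([0.0])
        assert predict_proba(model, {"d1": 3.0}) == 0.0

    def test_consensus_bounded_by_per_tree_fractions(self, sparse_data):
        dataset, _ = sparse_data
        model = train_forest(dataset)
        per_tree = np.array([_tree_fractions(t, dataset.table) for t in model.trees])
        consensus = np.array([p.probability for p in predict_table(model, dataset.table)])
        assert (consensus >= per_tree.min(axis=0) - 1e-12).all()
        assert (consensus <= per_tree.max(axis=0) + 1e-12).all()

    def test_missing_descriptor_is_named_in_error(self):
        model = self._two_leaf_model([0.5])
        with pytest.raises(KeyError, match="d1"):
            predict_proba(model, {"other": 1.0})

    @pytest.mark.parametrize("p, expected", [(0.5, BINDER), (0.49, NON_BINDER), (1.0, BINDER), (0.0, NON_BINDER)])
    def test_classify_boundary_inclusive(self, p, expected):
        assert classify(p) == expected

    def test_classify_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify(1.2)


class TestPersistence:
    def test_round_trip_preserves_predictions(self, sparse_data, tmp_path):
        dataset, _ = sparse_data
        model = train_forest(dataset)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        before = [p.probability for p in predict_table(model, dataset.table)]
        after = [p.probability for p in predict_table(back, dataset.table)]
        assert before == after
        assert back.descriptor_sets == model.descriptor_sets

    def test_truncated_file_is_schema_error(self, sparse_data, tmp_path):
        dataset, _ = sparse_data
        path = tmp_path / "model.json"
        save_model(train_forest(dataset), path)
        path.write_text(path.read_text()[: 50])
        with pytest.raises(ValueError):
            load_model(path)

    def test_reloaded_model_names_missing_descriptor(self, sparse_data, tmp_path):
        dataset, _ = sparse_data
        model = train_forest(dataset)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        used = sorted(back.used_descriptors())[0]
        keep = [n for n in dataset.table.descriptor_names if n != used]
        with pytest.raises(KeyError, match=used):
            predict_table(back, dataset.table.select_descriptors(keep))
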
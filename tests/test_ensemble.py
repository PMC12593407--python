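import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from atlkit.ensemble import (
    LEAF,
    LabeledSet,
    ModelConfig,
    ReactionRecord,
    combine,
    descriptor_usage,
    label_records,
    predict_improvement,
    prune_failed,
    train_forest_batch,
)
from atlkit.errors import DimensionError, TrainingError
from atlkit.reagent_space import Condition, enumerate_space

from conftest import leaf_tree, make_ensemble, stump


class TestReactionRecord:
    def test_yield_bounds(self):
        c = Condition("P1", "L1", "none", "S1")
        with pytest.raises(ValueError):
            ReactionRecord(("Am1", "Ac1"), c, 101.0, "source")
        with pytest.raises(ValueError):
            ReactionRecord(("Am1", "Ac1"), c, -1.0, "source")

    def test_domain_restricted(self):
        c = Condition("P1", "L1", "none", "S1")
        with pytest.raises(ValueError):
            ReactionRecord(("Am1", "Ac1"), c, 50.0, "other")


class TestLabelRecords:
    def _records(self, yields, toy_catalog):
        space = enumerate_space(toy_catalog)
        return [
            ReactionRecord(("Am1", "Ac1"), space[i], y, "source")
            for i, y in enumerate(yields)
        ]

    def test_improvement_labeled_positive(self, toy_catalog, toy_schema):
        data = label_records(
            self._records([65.0], toy_catalog), 55.0, schema=toy_schema, catalog=toy_catalog
        )
        assert data.y.tolist() == [1]
        assert data.threshold_percent == 55.0

    def test_strict_inequality_boundary(self, toy_catalog, toy_schema):
        data = label_records(
            self._records([55.0], toy_catalog), 55.0, schema=toy_schema, catalog=toy_catalog
        )
        assert data.y.tolist() == [0]

    def test_all_zero_yields(self, toy_catalog, toy_schema):
        data = label_records(
            self._records([0.0] * 5, toy_catalog), 10.0, schema=toy_schema, catalog=toy_catalog
        )
        assert data.y.sum() == 0

    def test_empty_records_error(self, toy_schema, toy_catalog):
        with pytest.raises(TrainingError):
            label_records([], 10.0, schema=toy_schema, catalog=toy_catalog)

    @settings(
        max_examples=30, deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        yields=st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=20),
        threshold=st.floats(min_value=0, max_value=100),
    )
    def test_label_rule_property(self, yields, threshold, toy_catalog, toy_schema):
        data = label_records(
            self._records(yields, toy_catalog), threshold,
            schema=toy_schema, catalog=toy_catalog,
        )
        expected = [1 if y > threshold else 0 for y in yields]
        assert data.y.tolist() == expected


def separable_set(n=60, seed=0, width=4):
    """Feature 0 perfectly separates classes; the rest is noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, width))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] = np.where(y == 1, X[:, 0] + 2.0, X[:, 0] - 2.0)
    return LabeledSet(X=X, y=y, threshold_percent=50.0)


class TestTrainForestBatch:
    def test_seeded_determinism(self):
        data = separable_set()
        cfg = ModelConfig(n_models=5, trees_per_model=4, max_depth=1, seed=3)
        a = train_forest_batch(data, cfg, generation=0)
        b = train_forest_batch(data, cfg, generation=0)
        assert [m.trees for m in a.members] == [m.trees for m in b.members]

    def test_member_count_and_generation(self):
        data = separable_set()
        cfg = ModelConfig(n_models=7, trees_per_model=3, seed=0)
        ens = train_forest_batch(data, cfg, generation=2)
        assert len(ens) == 7
        assert ens.generations == [2] * 7
        assert all(len(m.trees) == 3 for m in ens.members)

    def test_depth_bound(self):
        data = separable_set()
        cfg = ModelConfig(n_models=10, trees_per_model=5, max_depth=1, seed=1)
        ens = train_forest_batch(data, cfg, generation=0)
        for m in ens.members:
            for t in m.trees:
                assert len(t.split_features) <= 1

    def test_separable_feature_dominates_splits(self):
        # oracle: read split indices directly; feature 0 separates by construction
        data = separable_set(n=100, seed=5)
        cfg = ModelConfig(n_models=20, trees_per_model=5, max_depth=1, seed=2)
        ens = train_forest_batch(data, cfg, generation=0)
        splits = [f for m in ens.members for t in m.trees for f in t.split_features]
        frac = sum(1 for f in splits if f == 0) / len(splits)
        assert frac >= 0.95

    def test_single_class_fallback(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        data = LabeledSet(X=X, y=np.zeros(10, dtype=int), threshold_percent=20.0)
        ens = train_forest_batch(data, ModelConfig(n_models=3, trees_per_model=2, seed=0), 0)
        probs = predict_improvement(ens, X)
        np.testing.assert_array_equal(probs, 0.0)

    def test_empty_data_error(self):
        data = LabeledSet(X=np.empty((0, 3)), y=np.empty(0, dtype=int), threshold_percent=0)
        with pytest.raises(TrainingError):
            train_forest_batch(data, ModelConfig(n_models=2, trees_per_model=2, seed=0), 0)


class TestPredictImprovement:
    def test_identical_members_equal_probs(self, rng):
        t = stump(0, 0.0, 0.2, 0.8)
        ens = make_ensemble([[t], [t], [t]], n_features=3)
        p = predict_improvement(ens, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(p, 0.8)

    def test_probability_bounds_random_inputs(self, rng):
        trees = [[stump(i % 3, rng.normal(), rng.random(), rng.random())] for i in range(8)]
        ens = make_ensemble(trees, n_features=3)
        P = predict_improvement(ens, rng.normal(size=(50, 3)))
        assert P.shape == (8, 50)
        assert ((P >= 0) & (P <= 1)).all()

    def test_single_tree_routes_to_leaf_value(self):
        # derived by hand: x[1] = 2.0 > 0.5 -> right leaf (0.7)
        t = stump(1, 0.5, 0.1, 0.7)
        ens = make_ensemble([[t]], n_features=2)
        assert predict_improvement(ens, np.array([0.0, 2.0]))[0] == 0.7
        assert predict_improvement(ens, np.array([0.0, 0.5]))[0] == 0.1  # <= goes left

    def test_width_mismatch(self):
        ens = make_ensemble([[stump(0, 0.0, 0.2, 0.8)]], n_features=3)
        with pytest.raises(DimensionError):
            predict_improvement(ens, np.zeros(5))


class TestPruneFailed:
    def _ten_tree_ensemble(self):
        # trees 0..3 predict positive for x0 > 0; trees 4..9 predict negative always
        pos = [stump(0, 0.0, 0.1, 0.9) for _ in range(4)]
        neg = [stump(0, 0.0, 0.2, 0.4) for _ in range(6)]
        return make_ensemble([pos[:2], pos[2:] + neg[:1], neg[1:]], n_features=2)

    def test_tree_count_decreases_by_offenders(self):
        ens = self._ten_tree_ensemble()
        failed = np.array([[1.0, 0.0]])  # routed right on every stump
        # brute-force oracle: count trees whose routed prob > 0.5
        k = sum(
            1 for m in ens.members for t in m.trees
            if t.prob_pos[t.route(failed[0])] > 0.5
        )
        assert k == 4
        pruned = prune_failed(ens, failed)
        assert pruned.n_trees == ens.n_trees - k

    def test_no_failures_identity(self):
        ens = self._ten_tree_ensemble()
        assert prune_failed(ens, np.empty((0, 2))) is ens

    def test_no_offenders_identity(self):
        ens = self._ten_tree_ensemble()
        failed = np.array([[-1.0, 0.0]])  # all route left, max prob 0.2
        assert prune_failed(ens, failed) is ens

    def test_post_prune_zero_positive_votes(self):
        ens = self._ten_tree_ensemble()
        failed = np.array([[1.0, 0.0], [2.0, 5.0]])
        pruned = prune_failed(ens, failed)
        for m in pruned.members:
            for t in m.trees:
                assert (t.predict_proba(failed) <= 0.5).all()

    def test_idempotent(self):
        ens = self._ten_tree_ensemble()
        failed = np.array([[1.0, 0.0]])
        once = prune_failed(ens, failed)
        twice = prune_failed(once, failed)
        assert twice is once

    def test_empty_members_dropped(self):
        ens = make_ensemble([[stump(0, 0.0, 0.1, 0.9)], [stump(0, 0.0, 0.1, 0.4)]], 2)
        pruned = prune_failed(ens, np.array([[1.0, 0.0]]))
        assert len(pruned) == 1
        assert pruned.n_trees == 1

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_prune_idempotent_property(self, seed):
        rng = np.random.default_rng(seed)
        trees = [
            [stump(int(rng.integers(0, 3)), float(rng.normal()), float(rng.random()),
                   float(rng.random())) for _ in range(int(rng.integers(1, 4)))]
            for _ in range(5)
        ]
        ens = make_ensemble(trees, n_features=3)
        failed = rng.normal(size=(3, 3))
        once = prune_failed(ens, failed)
        assert prune_failed(once, failed) is once


class TestCombine:
    def test_identity_with_empty(self):
        from atlkit.ensemble import Ensemble

        e = make_ensemble([[stump(0, 0.0, 0.1, 0.9)]], 2)
        empty = Ensemble(members=[], n_features=2)
        assert combine(e, empty) is e
        assert combine(empty, e) is e

    def test_cardinality_and_tags(self):
        old = make_ensemble([[leaf_tree(0.0)]] * 3, 2, generation=0)
        new = make_ensemble([[leaf_tree(1.0)]] * 2, 2, generation=1)
        both = combine(old, new)
        assert len(both) == 5
        assert both.generations == [0, 0, 0, 1, 1]

    def test_width_mismatch(self):
        a = make_ensemble([[leaf_tree(0.0)]], 2)
        b = make_ensemble([[leaf_tree(0.0)]], 3)
        with pytest.raises(DimensionError):
            combine(a, b)


class TestDescriptorUsage:
    def test_hand_built_fractions(self, toy_schema):
        lig = toy_schema.block_slice("ligand").start
        sol = toy_schema.block_slice("solvent").start
        pre = toy_schema.block_slice("precatalyst").start
        trees = [
            [stump(lig, 0.0, 0.1, 0.9)],
            [stump(lig + 1, 0.0, 0.1, 0.9)],
            [stump(sol, 0.0, 0.1, 0.9)],
            [stump(pre, 0.0, 0.1, 0.9)],
        ]
        ens = make_ensemble(trees, n_features=toy_schema.width)
        usage = descriptor_usage(ens, toy_schema)
        assert usage == {"ligand": 0.5, "precatalyst": 0.25, "solvent": 0.25}

    def test_fractions_sum_to_one(self, toy_schema, rng):
        trees = [
            [stump(int(rng.integers(0, toy_schema.width)), 0.0, 0.1, 0.9)]
            for _ in range(12)
        ]
        ens = make_ensemble(trees, n_features=toy_schema.width)
        assert abs(sum(descriptor_usage(ens, toy_schema).values()) - 1.0) < 1e-12

    def test_all_ligand_splits(self, toy_schema):
        lig = toy_schema.block_slice("ligand").start
        ens = make_ensemble([[stump(lig, 0.0, 0.1, 0.9)]] * 3, toy_schema.width)
        assert descriptor_usage(ens, toy_schema) == {"ligand": 1.0}

    def test_leaf_only_stumps_contribute_nothing(self, toy_schema):
        lig = toy_schema.block_slice("ligand").start
        ens = make_ensemble(
            [[leaf_tree(0.0)], [stump(lig, 0.0, 0.1, 0.9)]], toy_schema.width
        )
        assert descriptor_usage(ens, toy_schema) == {"ligand": 1.0}

    def test_by_generation(self, toy_schema):
        lig = toy_schema.block_slice("ligand").start
        sol = toy_schema.block_slice("solvent").start
        g0 = make_ensemble([[stump(lig, 0.0, 0.1, 0.9)]], toy_schema.width, generation=0)
        g1 = make_ensemble([[stump(sol, 0.0, 0.1, 0.9)]], toy_schema.width, generation=1)
        both = combine(g0, g1)
        usage = descriptor_usage(both, toy_schema, by_generation=True)
        assert usage == {0: {"ligand": 1.0}, 1: {"solvent": 1.0}}
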
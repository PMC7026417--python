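import numpy as np
import pytest

from connsel.fsriel import (
    LEARNER_IDS,
    FoBaConfig,
    FSRIELConfig,
    ImportanceRanking,
    exhaustive_subset_search,
    fit_ensemble,
    foba_select,
    fsriel_fit,
    nested_tune,
    pool_union,
    rank_importance,
    select_top_fraction,
)

from conftest import planted_feature


class TestRankImportance:
    @pytest.mark.parametrize("learner_id", LEARNER_IDS)
    def test_planted_feature_ranks_first(self, learner_id):
        """A feature that is the label plus tiny noise dominates every ranker."""
        rng = np.random.default_rng(42)
        X, y, _ = planted_feature(rng, n=80, e=12, effect=2.0, noise=0.05)
        r = rank_importance(X, y, learner_id, seed=3)
        assert int(np.argmax(r.importances)) == 0
        assert r.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(r.importances >= 0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X, y, _ = planted_feature(rng, n=60, e=20, effect=1.0, noise=0.5)
        a = rank_importance(X, y, "random_forest", seed=9)
        b = rank_importance(X, y, "random_forest", seed=9)
        assert np.array_equal(a.importances, b.importances)

    def test_pure_noise_rank_not_concentrated(self):
        """Without signal, no fixed feature should dominate across seeds."""
        rng = np.random.default_rng(7)
        winners = []
        for seed in range(8):
            X = rng.standard_normal((60, 50))
            y = np.repeat([0, 1], 30)
            r = rank_importance(X, y, "extra_trees", seed=seed)
            winners.append(int(np.argmax(r.importances)))
        assert len(set(winners)) >= 4  # winner wanders under the null

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            rank_importance(np.ones((10, 3)), np.zeros(10), "random_forest")


class TestSelectTopFraction:
    @pytest.mark.parametrize(
        "e,fraction,expected_k",
        [(100, 0.02, 2), (37128, 0.02, 742), (10, 0.2, 2), (3, 0.02, 1)],
    )
    def test_k_rule(self, e, fraction, expected_k):
        r = ImportanceRanking("extra_trees", np.full(e, 1.0 / e))
        assert select_top_fraction(r, fraction).size == expected_k

    def test_tie_break_ascending_index(self):
        r = ImportanceRanking("extra_trees", np.full(10, 0.1))
        assert select_top_fraction(r, 0.2).tolist() == [0, 1]

    def test_selects_highest(self):
        imp = np.zeros(50)
        imp[[17, 31]] = 0.5
        r = ImportanceRanking("extra_trees", imp)
        assert select_top_fraction(r, 0.04).tolist() == [17, 31]


class TestPoolUnion:
    def test_union_and_provenance(self):
        pool = pool_union({"a": [1, 2], "b": [2, 3], "c": [], "d": [], "e": []})
        assert pool.indices.tolist() == [1, 2, 3]
        assert pool.provenance[2] == {"a", "b"}

    def test_identical_and_disjoint(self):
        same = pool_union([np.arange(5)] * 5)
        assert len(same) == 5
        disjoint = pool_union([np.arange(i * 3, i * 3 + 3) for i in range(5)])
        assert len(disjoint) == 15


class TestFoBa:
    def test_planted_informative_recovered(self):
        """One strongly informative + 9 noise: the informative one is chosen."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X, y, _ = planted_feature(rng, n=80, e=10, effect=3.0, noise=0.3)
            res = foba_select(X, y, list(range(10)), FoBaConfig(seed=seed))
            if res.selected == [0]:
                hits += 1
        assert hits >= 18

    def test_duplicate_feature_not_kept_twice(self):
        """Under the accuracy objective a duplicate adds nothing, so at most
        one copy survives. (Under the hinge objective a duplicated column
        halves its effective L2 penalty and can legitimately be retained.)"""
        rng = np.random.default_rng(3)
        X, y, _ = planted_feature(rng, n=80, e=6, effect=3.0, noise=0.3)
        X[:, 1] = X[:, 0]  # exact duplicate of the informative feature
        res = foba_select(X, y, list(range(6)), FoBaConfig(seed=0, objective="accuracy"))
        assert not {0, 1} <= set(res.selected)

    def test_forward_objective_nondecreasing(self):
        rng = np.random.default_rng(9)
        X, y, _ = planted_feature(rng, n=60, e=8, effect=1.0, noise=1.0, informative=3)
        res = foba_select(X, y, list(range(8)), FoBaConfig(seed=1))
        fwd = [obj for step, _, obj in res.trace if step == "forward"]
        assert all(b >= a - 1e-12 for a, b in zip(fwd, fwd[1:]))

    def test_no_signal_stopping_rule(self):
        """Null data: the trace records the stopping decision; selection stays small."""
        rng = np.random.default_rng(11)
        X = rng.standard_normal((40, 8))
        y = np.repeat([0, 1], 20)
        res = foba_select(X, y, list(range(8)), FoBaConfig(seed=2, max_features=4))
        assert len(res.selected) <= 4
        assert np.isfinite(res.objective)

    def test_constant_column_skipped(self):
        rng = np.random.default_rng(5)
        X, y, _ = planted_feature(rng, n=40, e=5, effect=3.0, noise=0.3)
        X[:, 3] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            res = foba_select(X, y, list(range(5)), FoBaConfig(seed=0))
        assert 3 not in res.selected

    def test_matches_exhaustive_on_separable_instance(self):
        """Value equivalence with exhaustive search is checked under the
        accuracy objective, whose optimum (perfect classification) is exactly
        identifiable on a separable instance."""
        rng = np.random.default_rng(21)
        X, y, _ = planted_feature(rng, n=60, e=8, effect=3.0, noise=0.25)
        cfg = FoBaConfig(seed=4, objective="accuracy")
        res = foba_select(X, y, list(range(8)), cfg)
        _, best_obj = exhaustive_subset_search(X, y, list(range(8)), cfg)
        assert res.objective == pytest.approx(best_obj, abs=1e-6)


class TestNestedTune:
    def test_single_point_grid(self):
        rng = np.random.default_rng(0)
        X, y, _ = planted_feature(rng, n=30, e=4, effect=2.0, noise=0.3)
        assert nested_tune(X, y, grid=[0.5]) == 0.5

    def test_tie_returns_first_in_grid_order(self):
        rng = np.random.default_rng(1)
        X, y, _ = planted_feature(rng, n=30, e=2, effect=5.0, noise=0.1)
        # clean separable data: all C values tie at accuracy 1 -> first returned
        assert nested_tune(X, y, grid=[10.0, 0.1]) == 10.0

    def test_moderate_beats_absurd_regularization(self):
        rng = np.random.default_rng(2)
        X, y, _ = planted_feature(rng, n=60, e=30, effect=0.8, noise=1.0, informative=5)
        assert nested_tune(X, y, grid=[1e-7, 1.0], seed=0) == 1.0

    def test_too_small_for_folds(self):
        with pytest.raises(ValueError, match="stratified"):
            nested_tune(np.ones((4, 2)), np.array([0, 0, 1, 1]), inner_k=3)


class TestEnsemble:
    def test_separable_toy_training_accuracy(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [0.2, 0.1],
                      [5, 5], [5, 6], [6, 5], [5.2, 5.1]], dtype=float)
        y = np.array(["control"] * 4 + ["case"] * 4)
        ens = fit_ensemble(X, y, seed=0)
        assert np.array_equal(ens.predict(X), y)

    def test_majority_rule_three_to_two(self):
        """Vote is 'case' whenever 3 of the 5 members say case."""

        class Stub:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        from connsel.fsriel import EnsembleClassifier

        ens = EnsembleClassifier(
            {f"m{i}": Stub(1 if i < 3 else 0) for i in range(5)},
            classes=np.array(["control", "case"]),
        )
        assert ens.predict(np.zeros((2, 1))).tolist() == ["case", "case"]

    def test_empty_subspace_rejected(self):
        with pytest.raises(ValueError, match="at least one feature"):
            fit_ensemble(np.empty((10, 0)), np.repeat([0, 1], 5))


@pytest.fixture(scope="module")
def planted_data():
    rng = np.random.default_rng(77)
    n, e = 100, 300
    y = np.repeat(["control", "case"], n // 2)
    X = rng.standard_normal((n, e))
    planted = [10, 60, 110, 160, 210]
    mask = y == "case"
    for j in planted:
        X[mask, j] += 1.5
    return X, y, planted


class TestFullPipeline:

    def test_planted_edges_selected_and_heldout_accuracy(self, planted_data):
        X, y, planted = planted_data
        rng = np.random.default_rng(1234)
        perm = rng.permutation(len(y))
        train, test = perm[:70], perm[70:]
        model = fsriel_fit(X[train], y[train], FSRIELConfig(seed=5))
        assert set(model.selected) <= set(model.pool.indices.tolist())
        assert len(set(model.selected) & set(planted)) >= 2
        acc = np.mean(model.predict(X[test]) == y[test])
        assert acc >= 0.9

    def test_selected_subset_of_pool_and_bound(self, planted_data):
        X, y, _ = planted_data
        model = fsriel_fit(X, y, FSRIELConfig(seed=6))
        k = max(1, int(0.02 * X.shape[1]))
        assert len(model.pool) <= 5 * k
        assert set(model.selected) <= set(model.pool.indices.tolist())

    def test_reproducible_given_seed(self, planted_data):
        X, y, _ = planted_data
        a = fsriel_fit(X, y, FSRIELConfig(seed=9))
        b = fsriel_fit(X, y, FSRIELConfig(seed=9))
        assert a.selected == b.selected
        assert a.tuned_C == b.tuned_C

    def test_label_interchange_flips_vote(self):
        """Relabeling symmetry: inverting every member's vote inverts the output."""
        from connsel.fsriel import EnsembleClassifier

        rng = np.random.default_rng(0)
        votes = rng.integers(0, 2, size=(5, 12))

        class Stub:
            def __init__(self, row):
                self.row = row

            def predict(self, X):
                return self.row[: len(X)]

        classes = np.array(["control", "case"])
        ens = EnsembleClassifier({f"m{i}": Stub(votes[i]) for i in range(5)}, classes)
        flipped = EnsembleClassifier({f"m{i}": Stub(1 - votes[i]) for i in range(5)}, classes)
        X = np.zeros((12, 1))
        p, q = ens.predict(X), flipped.predict(X)
        assert np.array_equal(p == "case", q == "control")
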
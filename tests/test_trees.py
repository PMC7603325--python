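"""Cost-weighted tree induction, footprint accounting, selection, I/O."""

import numpy as np
import pytest

from aioa.errors import BudgetInfeasibleError, SchemaError, ValidationError
from aioa.features import CatalogueEntry, FeatureCatalogue
from aioa.trees import (
    CostedTree,
    InductionParams,
    Leaf,
    Node,
    compute_weights,
    estimate_tree_size,
    generate_batch,
    grow_tree,
    load_model,
    pareto_frontier,
    sample_candidates,
    save_model,
    select_tree,
    uniform_weights,
)


def _cat(sizes):
    return FeatureCatalogue({k: CatalogueEntry(extractor="mean", size_bytes=v)
                             for k, v in sizes.items()})


class TestWeights:
    def test_inverse_size_normalisation(self):
        w = compute_weights(_cat({"A": 100, "B": 200, "C": 700}))
        assert w["A"] == pytest.approx(0.6087, abs=5e-5)
        assert w["B"] == pytest.approx(0.3043, abs=5e-5)
        assert w["C"] == pytest.approx(0.0870, abs=5e-5)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_equal_sizes_give_uniform_weights(self):
        w = compute_weights(_cat({"A": 50, "B": 50, "C": 50}))
        assert all(v == pytest.approx(1 / 3) for v in w.values())

    def test_single_feature_weight_one(self):
        assert compute_weights(_cat({"A": 10}))["A"] == 1.0

    def test_cheaper_feature_never_loses_weight(self, rng):
        """Monotonicity: shrinking a feature's size grows its weight."""
        sizes = {"A": 300, "B": 150, "C": 90}
        w0 = compute_weights(_cat(sizes))["A"]
        for smaller in (200, 100, 50):
            sizes["A"] = smaller
            assert compute_weights(_cat(sizes))["A"] > w0
            w0 = compute_weights(_cat(sizes))["A"]

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValidationError):
            _cat({"A": 0})


class TestCandidateSampling:
    def test_full_draw_returns_every_feature(self, rng):
        w = compute_weights(_cat({"A": 1, "B": 2, "C": 3}))
        assert set(sample_candidates(w, 3, rng)) == {"A", "B", "C"}

    def test_oversized_draw_rejected(self, rng):
        w = compute_weights(_cat({"A": 1}))
        with pytest.raises(ValidationError):
            sample_candidates(w, 2, rng)

    def test_fixed_seed_reproducible(self):
        w = compute_weights(_cat({"A": 100, "B": 200, "C": 700, "D": 90}))
        a = sample_candidates(w, 2, np.random.default_rng(7))
        b = sample_candidates(w, 2, np.random.default_rng(7))
        assert a == b

    def test_single_draw_frequency_matches_weight(self):
        """Monte-Carlo check of the analytic selection probability."""
        w = compute_weights(_cat({"A": 100, "B": 200, "C": 700}))
        rng = np.random.default_rng(0)
        n = 100_000
        hits = sum(sample_candidates(w, 1, rng)[0] == "A" for _ in range(n))
        assert hits / n == pytest.approx(0.6087, abs=0.01)


@pytest.fixture(scope="module")
def toy_separable():
    rng = np.random.default_rng(5)
    n = 120
    y = np.array(["stationary"] * 60 + ["flying"] * 60, dtype=object)
    X = np.column_stack([
        np.where(y == "flying", 2.0, 0.0) + rng.normal(0, 0.1, n),
        rng.normal(0, 1, n),
    ])
    return X, y


class TestGrowTree:
    def test_separable_data_fits_perfectly(self, toy_separable):
        X, y = toy_separable
        cat = _cat({"f0": 100, "f1": 100})
        tree = grow_tree(X, y, ["f0", "f1"], cat, InductionParams(mtry=2),
                         np.random.default_rng(0))
        assert (tree.predict_table(X, ["f0", "f1"]) == y).mean() == 1.0

    def test_single_class_gives_single_leaf(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array(["flying"] * 20, dtype=object)
        cat = _cat({"f0": 1, "f1": 1})
        tree = grow_tree(X, y, ["f0", "f1"], cat, InductionParams(),
                         np.random.default_rng(0))
        assert isinstance(tree.root, Leaf) and tree.root.klass == "flying"

    def test_empty_training_set_rejected(self):
        cat = _cat({"f0": 1})
        with pytest.raises(ValidationError):
            grow_tree(np.empty((0, 1)), [], ["f0"], cat, InductionParams(),
                      np.random.default_rng(0))

    def test_matches_reference_single_tree_learner(self, gull_table, catalogue):
        """Uniform-weight induction is statistically equivalent to a
        reference random-forest-style single tree on the same data."""
        from sklearn.model_selection import train_test_split
        from sklearn.tree import DecisionTreeClassifier

        X, y = gull_table
        Xtr, Xte, ytr, yte = train_test_split(
            X, y.astype(str), test_size=0.5, random_state=0, stratify=y.astype(str))
        names = catalogue.names
        w = uniform_weights(catalogue)
        params = InductionParams(min_samples_leaf=5)
        diffs = []
        for seed in range(50):
            ours = grow_tree(Xtr, ytr, names, catalogue, params,
                             np.random.default_rng(seed), w)
            acc_ours = (ours.predict_table(Xte, names) == yte).mean()
            ref = DecisionTreeClassifier(max_features="sqrt", min_samples_leaf=5,
                                         random_state=seed).fit(Xtr, ytr)
            acc_ref = (ref.predict(Xte) == yte).mean()
            diffs.append(acc_ours - acc_ref)
        assert abs(np.mean(diffs)) < 0.02


class TestPredict:
    def test_single_leaf_constant(self):
        tree = CostedTree(Leaf("stationary"), ("stationary",))
        assert tree.predict_one({}) == "stationary"

    def test_boundary_value_goes_left(self):
        tree = CostedTree(Node("crest", 1.5, Leaf("stationary"), Leaf("flying")),
                          ("flying", "stationary"))
        assert tree.predict_one({"crest": 1.5}) == "stationary"
        assert tree.predict_one({"crest": 1.5000001}) == "flying"

    def test_missing_feature_named_in_error(self):
        tree = CostedTree(Node("crest", 1.5, Leaf("stationary"), Leaf("flying")),
                          ("flying", "stationary"))
        with pytest.raises(ValidationError, match="crest"):
            tree.predict_one({"mean": 1.0})

    def test_against_naive_descent_oracle(self, rng):
        """1000 random vectors through a random tree vs a recursive oracle."""
        names = [f"f{i}" for i in range(6)]

        def random_tree(depth):
            if depth == 0 or rng.random() < 0.3:
                return Leaf(str(rng.choice(["a", "b", "c"])))
            return Node(str(rng.choice(names)), float(rng.normal()),
                        random_tree(depth - 1), random_tree(depth - 1))

        tree = CostedTree(random_tree(4), ("a", "b", "c"))

        def oracle(node, fv):
            if isinstance(node, Leaf):
                return node.klass
            branch = node.left if fv[node.feature] <= node.threshold else node.right
            return oracle(branch, fv)

        X = rng.normal(size=(1000, 6))
        vec = tree.predict_table(X, names)
        for i in range(1000):
            fv = dict(zip(names, X[i]))
            assert tree.predict_one(fv) == oracle(tree.root, fv) == vec[i]


class TestFootprint:
    def test_repeated_feature_counted_once(self):
        root = Node("kurtosis", 1.0,
                    Node("kurtosis", 0.5, Leaf("a"), Leaf("b")), Leaf("c"))
        tree = CostedTree(root, ("a", "b", "c"))
        assert estimate_tree_size(tree, _cat({"kurtosis": 680})) == 680

    def test_distinct_features_summed(self):
        root = Node("kurtosis", 1.0, Leaf("a"), Node("mean", 0.2, Leaf("a"), Leaf("b")))
        tree = CostedTree(root, ("a", "b"))
        assert estimate_tree_size(tree, _cat({"kurtosis": 680, "mean": 120})) == 800

    def test_single_leaf_costs_only_overhead(self):
        tree = CostedTree(Leaf("a"), ("a",))
        assert estimate_tree_size(tree, _cat({"mean": 120})) == 0
        assert estimate_tree_size(tree, _cat({"mean": 120}),
                                  node_overhead_bytes=16) == 16

    def test_unknown_feature_rejected(self):
        tree = CostedTree(Node("fft_peak", 0.0, Leaf("a"), Leaf("b")), ("a", "b"))
        with pytest.raises(SchemaError, match="fft_peak"):
            estimate_tree_size(tree, _cat({"mean": 120}))


class TestBatchAndSelection:
    def test_infinite_threshold_keeps_all(self, gull_table, catalogue):
        X, y = gull_table
        batch = generate_batch(X, y, catalogue.names, catalogue,
                               InductionParams(), float("inf"), 5,
                               np.random.default_rng(0), cv=2)
        assert len(batch) == 5

    def test_impossible_budget_raises_with_smallest_size(self, gull_table, catalogue):
        X, y = gull_table
        with pytest.raises(BudgetInfeasibleError) as exc:
            generate_batch(X, y, catalogue.names, catalogue, InductionParams(),
                           50, 3, np.random.default_rng(0), attempt_cap=6)
        assert exc.value.smallest_size_bytes > 50

    def test_batch_respects_threshold(self, gull_table, catalogue):
        X, y = gull_table
        batch = generate_batch(X, y, catalogue.names, catalogue,
                               InductionParams(), 1000, 8,
                               np.random.default_rng(1), cv=2)
        assert all(t.estimated_size_bytes <= 1000 for t in batch)

    def test_selection_tie_breaks_to_smaller_tree(self):
        t1 = CostedTree(Leaf("a"), ("a",), estimated_size_bytes=900,
                        estimated_accuracy=0.90)
        t2 = CostedTree(Leaf("a"), ("a",), estimated_size_bytes=800,
                        estimated_accuracy=0.90)
        assert select_tree([t1, t2]) is t2

    def test_batch_of_one(self):
        t = CostedTree(Leaf("a"), ("a",), 100, 0.5)
        assert select_tree([t]) is t

    def test_selected_tree_is_nondominated(self, rng):
        batch = [CostedTree(Leaf("a"), ("a",),
                            int(rng.integers(100, 2000)), float(rng.random()))
                 for _ in range(30)]
        best = select_tree(batch)
        # brute-force dominance check: nothing is at least as accurate AND smaller
        for t in batch:
            assert not (t.estimated_accuracy >= best.estimated_accuracy
                        and t.estimated_size_bytes < best.estimated_size_bytes)
        front = pareto_frontier(batch)
        for f in front:
            dominated = any(
                (o.estimated_size_bytes <= f.estimated_size_bytes
                 and o.estimated_accuracy >= f.estimated_accuracy
                 and (o.estimated_size_bytes < f.estimated_size_bytes
                      or o.estimated_accuracy > f.estimated_accuracy))
                for o in batch)
            assert not dominated


class TestSerialization:
    def test_single_leaf_round_trip(self, tmp_path):
        tree = CostedTree(Leaf("stationary"), ("stationary",), 0, 1.0)
        p = tmp_path / "m.json"
        save_model(tree, p)
        back = load_model(p)
        assert isinstance(back.root, Leaf) and back.root.klass == "stationary"

    def test_round_trip_predicts_identically(self, tmp_path, rng):
        root = Node("mean", 1.0,
                    Node("crest", 1.4, Leaf("stationary"), Leaf("flying")),
                    Node("variance", 0.3, Leaf("flying"), Leaf("foraging")))
        tree = CostedTree(root, ("flying", "foraging", "stationary"), 640, 0.93)
        p = tmp_path / "m.json"
        save_model(tree, p)
        back = load_model(p)
        names = ["mean", "crest", "variance"]
        X = rng.normal(1.0, 0.6, size=(1000, 3))
        assert (tree.predict_table(X, names) == back.predict_table(X, names)).all()
        assert back.estimated_size_bytes == 640

    def test_unknown_feature_on_load_is_schema_error(self, tmp_path):
        tree = CostedTree(Node("fft_peak", 0.1, Leaf("a"), Leaf("b")), ("a", "b"))
        p = tmp_path / "m.json"
        save_model(tree, p)
        with pytest.raises(SchemaError, match="fft_peak"):
            load_model(p, _cat({"mean": 120}))
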
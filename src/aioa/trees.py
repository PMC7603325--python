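"""Memory-budgeted randomized decision-tree induction.

The learner is a CART-style tree with one twist borrowed from random
forests: at every node only a random subset of ``mtry`` features is
compared — but the subset is drawn *without replacement with probability
proportional to the inverse of each feature's program-memory byte cost*.
Cheap features are therefore offered as split candidates more often, and
the resulting trees tend to reference only inexpensive extractor code.

A tree's memory footprint is estimated as the sum of the byte costs of the
*distinct* features it references (extractor code is shared across nodes on
an MCU), plus an optional per-node overhead (default 0).  Batch generation
keeps growing trees until enough fall under a byte threshold, estimates
each survivor's accuracy by stratified cross-validation, and the final
deployed artifact is a single selected tree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import BudgetInfeasibleError, SchemaError, ValidationError
from .features import FeatureCatalogue

MODEL_FORMAT = "aioa-tree"
MODEL_VERSION = 1


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class Leaf:
    klass: str


@dataclass
class Node:
    feature: str
    threshold: float
    left: "Node | Leaf"
    right: "Node | Leaf"


@dataclass
class CostedTree:
    """A binary decision tree annotated with footprint and accuracy."""

    root: Node | Leaf
    classes: tuple[str, ...]
    estimated_size_bytes: int = 0
    estimated_accuracy: float = float("nan")

    def features_used(self) -> set[str]:
        out: set[str] = set()

        def walk(n):
            if isinstance(n, Node):
                out.add(n.feature)
                walk(n.left)
                walk(n.right)

        walk(self.root)
        return out

    def n_nodes(self) -> int:
        def walk(n):
            if isinstance(n, Leaf):
                return 1
            return 1 + walk(n.left) + walk(n.right)

        return walk(self.root)

    def predict_one(self, features) -> str:
        """Classify one window from a feature mapping.

        ``features`` may be a dict or a callable ``name -> value``; with a
        callable, only features on the taken root-to-leaf path are ever
        requested — mirroring on-demand extraction on the MCU.  Values equal
        to the threshold go left.
        """
        getter = features if callable(features) else features.__getitem__
        node = self.root
        while isinstance(node, Node):
            try:
                v = getter(node.feature)
            except KeyError:
                raise ValidationError(
                    f"feature {node.feature!r} required by the tree is missing"
                ) from None
            node = node.left if v <= node.threshold else node.right
        return node.klass

    def predict_table(self, X: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
        """Vectorised classification of an (n, p) feature table."""
        idx = {name: j for j, name in enumerate(feature_names)}
        n = X.shape[0]
        out = np.empty(n, dtype=object)
        stack = [(self.root, np.arange(n))]
        while stack:
            node, rows = stack.pop()
            if len(rows) == 0:
                continue
            if isinstance(node, Leaf):
                out[rows] = node.klass
                continue
            if node.feature not in idx:
                raise ValidationError(
                    f"feature {node.feature!r} required by the tree is missing")
            mask = X[rows, idx[node.feature]] <= node.threshold
            stack.append((node.left, rows[mask]))
            stack.append((node.right, rows[~mask]))
        return out


def predict(tree: CostedTree, features) -> str:
    """Functional alias for :meth:`CostedTree.predict_one`."""
    return tree.predict_one(features)


# ---------------------------------------------------------------------------
# Cost weights and candidate sampling


def compute_weights(catalogue: FeatureCatalogue) -> dict[str, float]:
    """Selection weight per feature, proportional to 1/size_bytes, sum 1."""
    inv = {}
    for name in catalogue.names:
        size = catalogue.size_bytes(name)
        if size <= 0:
            raise ValidationError(f"feature {name!r}: size must be positive")
        inv[name] = 1.0 / size
    total = sum(inv.values())
    return {name: v / total for name, v in inv.items()}


def uniform_weights(catalogue: FeatureCatalogue) -> dict[str, float]:
    n = len(catalogue)
    return {name: 1.0 / n for name in catalogue.names}


def sample_candidates(weights: dict[str, float], m: int,
                      rng: np.random.Generator) -> list[str]:
    """Draw ``m`` distinct features, sequential weighted draws w/o replacement.

    Each draw picks a feature with probability proportional to the weights
    of the features still available (renormalisation happens implicitly).
    """
    names = list(weights)
    if m > len(names):
        raise ValidationError(f"m={m} exceeds the {len(names)} available features")
    w = np.array([weights[n] for n in names], dtype=float)
    if np.any(w <= 0):
        raise ValidationError("weights must be strictly positive")
    chosen: list[str] = []
    avail = list(range(len(names)))
    for _ in range(m):
        wa = w[avail]
        probs = wa / wa.sum()
        j = int(rng.choice(len(avail), p=probs))
        chosen.append(names[avail[j]])
        del avail[j]
    return chosen


# ---------------------------------------------------------------------------
# Induction


@dataclass
class InductionParams:
    """Knobs of the randomized induction.

    ``mtry`` defaults to ceil(sqrt(p)) — the random-forest convention.
    Splits use Gini impurity; a node is split only if both children keep at
    least ``min_samples_leaf`` samples and the impurity strictly decreases.
    """

    mtry: int | None = None
    min_samples_leaf: int = 5
    max_depth: int | None = None

    def resolved_mtry(self, n_features: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, math.ceil(math.sqrt(n_features)))
        if not (1 <= m <= n_features):
            raise ValidationError(f"mtry={m} outside [1, {n_features}]")
        return m


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _best_split_feature(x: np.ndarray, y: np.ndarray, n_classes: int,
                        min_leaf: int):
    """Best (impurity_decrease, threshold) splitting one feature, or None."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    parent = _gini(total)
    # candidate split after position i (left gets i+1 samples)
    i = np.arange(min_leaf - 1, n - min_leaf)
    if len(i) == 0:
        return None
    distinct = xs[i] < xs[i + 1]
    i = i[distinct]
    if len(i) == 0:
        return None
    nl = (i + 1).astype(float)
    nr = n - nl
    left = cum[i]
    right = total - left
    gl = 1.0 - ((left / nl[:, None]) ** 2).sum(axis=1)
    gr = 1.0 - ((right / nr[:, None]) ** 2).sum(axis=1)
    weighted = (nl * gl + nr * gr) / n
    dec = parent - weighted
    k = int(np.argmax(dec))
    if dec[k] <= 1e-12:
        return None
    thr = (xs[i[k]] + xs[i[k] + 1]) / 2.0
    return float(dec[k]), float(thr)


def grow_tree(X: np.ndarray, y: Sequence[str], feature_names: Sequence[str],
              catalogue: FeatureCatalogue, params: InductionParams,
              rng: np.random.Generator,
              weights: dict[str, float] | None = None) -> CostedTree:
    """Grow one randomized, cost-aware decision tree.

    ``weights`` defaults to inverse-size weights from the catalogue; pass
    :func:`uniform_weights` for the unweighted (plain random-forest)
    variant.  Split-quality ties break toward the cheaper feature, then the
    lexicographically earlier name, so builds are deterministic under a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.shape[0] == 0:
        raise ValidationError("empty training set")
    if X.shape[0] != len(y):
        raise ValidationError("feature table and labels disagree in length")
    missing = [f for f in feature_names if f not in catalogue]
    if missing:
        raise ValidationError(f"features not in catalogue: {missing}")
    classes = tuple(sorted(set(map(str, y))))
    code = {c: k for k, c in enumerate(classes)}
    yc = np.array([code[str(v)] for v in y])
    weights = weights if weights is not None else compute_weights(catalogue)
    weights = {f: weights[f] for f in feature_names}
    col = {f: j for j, f in enumerate(feature_names)}
    mtry = params.resolved_mtry(len(feature_names))
    min_leaf = params.min_samples_leaf

    def majority(rows) -> Leaf:
        counts = np.bincount(yc[rows], minlength=len(classes))
        return Leaf(classes[int(np.argmax(counts))])

    def build(rows: np.ndarray, depth: int):
        counts = np.bincount(yc[rows], minlength=len(classes))
        if (counts > 0).sum() <= 1 or len(rows) < 2 * min_leaf or \
                (params.max_depth is not None and depth >= params.max_depth):
            return majority(rows)
        candidates = sample_candidates(weights, mtry, rng)
        # evaluate in (size, name) order so exact ties go to cheaper features
        candidates.sort(key=lambda f: (catalogue.size_bytes(f), f))
        best = None
        for f in candidates:
            res = _best_split_feature(X[rows, col[f]], yc[rows], len(classes), min_leaf)
            if res is None:
                continue
            dec, thr = res
            if best is None or dec > best[0]:
                best = (dec, f, thr)
        if best is None:
            return majority(rows)
        _, f, thr = best
        mask = X[rows, col[f]] <= thr
        return Node(f, thr, build(rows[mask], depth + 1), build(rows[~mask], depth + 1))

    root = build(np.arange(X.shape[0]), 0)
    tree = CostedTree(root, classes)
    tree.estimated_size_bytes = estimate_tree_size(tree, catalogue)
    return tree


def estimate_tree_size(tree: CostedTree, catalogue: FeatureCatalogue,
                       node_overhead_bytes: int = 0) -> int:
    """Footprint estimate: distinct-feature byte costs plus node overhead.

    Distinct features are counted once because extractor code is shared by
    all nodes referencing the same feature.  ``node_overhead_bytes`` is
    charged per tree node (internal and leaf) for the conditional logic
    itself; it defaults to 0.
    """
    total = 0
    for f in tree.features_used():
        if f not in catalogue:
            raise SchemaError(f"tree references feature {f!r} absent from catalogue")
        total += catalogue.size_bytes(f)
    return total + node_overhead_bytes * tree.n_nodes()


# ---------------------------------------------------------------------------
# Accuracy estimation, batch generation, selection


def crossval_accuracy(X, y, feature_names, catalogue, params, rng,
                      weights=None, n_splits: int = 5) -> float:
    """Stratified k-fold CV accuracy of freshly grown trees."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    _, counts = np.unique(y.astype(str), return_counts=True)
    n_splits = int(min(n_splits, counts.min()))
    if n_splits < 2:
        return float((grow_tree(X, y, feature_names, catalogue, params, rng,
                                weights).predict_table(X, feature_names) == y).mean())
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    accs = []
    for tr, te in skf.split(X, y.astype(str)):
        t = grow_tree(X[tr], y[tr], feature_names, catalogue, params, rng, weights)
        accs.append(float((t.predict_table(X[te], feature_names) == y[te]).mean()))
    return float(np.mean(accs))


def generate_batch(X, y, feature_names, catalogue, params,
                   size_threshold: float, n_trees: int,
                   rng: np.random.Generator, weights=None,
                   attempt_cap: int | None = None, cv: int = 5,
                   node_overhead_bytes: int = 0) -> list[CostedTree]:
    """Grow trees until ``n_trees`` fit under ``size_threshold`` bytes.

    Oversized trees are discarded.  Each retained tree carries a
    cross-validated ``estimated_accuracy``.  If the attempt cap (default
    ``20 * n_trees``) is reached with no qualifying tree, the budget is
    infeasible and the smallest footprint seen is reported.
    """
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    attempt_cap = attempt_cap if attempt_cap is not None else 20 * n_trees
    kept: list[CostedTree] = []
    smallest = None
    attempts = 0
    while len(kept) < n_trees and attempts < attempt_cap:
        attempts += 1
        tree = grow_tree(X, y, feature_names, catalogue, params, rng, weights)
        size = estimate_tree_size(tree, catalogue, node_overhead_bytes)
        tree.estimated_size_bytes = size
        smallest = size if smallest is None else min(smallest, size)
        if size <= size_threshold:
            tree.estimated_accuracy = crossval_accuracy(
                X, y, feature_names, catalogue, params, rng, weights, cv)
            kept.append(tree)
    if not kept:
        raise BudgetInfeasibleError(
            f"no tree under {size_threshold} bytes in {attempts} attempts; "
            f"smallest tree seen was {smallest} bytes",
            smallest_size_bytes=smallest,
        )
    return kept


def pareto_frontier(batch: Sequence[CostedTree]) -> list[CostedTree]:
    """Non-dominated trees in (size ↓, accuracy ↑), sorted by size."""
    if not batch:
        raise ValidationError("empty batch")
    ordered = sorted(batch, key=lambda t: (t.estimated_size_bytes,
                                           -t.estimated_accuracy))
    front: list[CostedTree] = []
    best_acc = -np.inf
    for t in ordered:
        if t.estimated_accuracy > best_acc:
            front.append(t)
            best_acc = t.estimated_accuracy
    return front


@dataclass
class ParetoSelection:
    frontier: list[CostedTree]
    best: CostedTree


def select_tree(batch: Sequence[CostedTree], strategy: str = "max_accuracy"):
    """Pick the deployed tree from a qualifying batch.

    ``max_accuracy``: highest estimated accuracy, ties to the smaller
    footprint.  ``pareto``: the full non-dominated (size, accuracy)
    frontier together with the max-accuracy member.
    """
    if not batch:
        raise ValidationError("empty batch")
    best = min(batch, key=lambda t: (-t.estimated_accuracy, t.estimated_size_bytes))
    if strategy == "max_accuracy":
        return best
    if strategy == "pareto":
        return ParetoSelection(pareto_frontier(batch), best)
    raise ValidationError(f"unknown selection strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Serialization (versioned JSON text format; see docs/methods.md)


def _node_to_obj(node):
    if isinstance(node, Leaf):
        return {"type": "leaf", "class": node.klass}
    return {"type": "node", "feature": node.feature, "threshold": node.threshold,
            "left": _node_to_obj(node.left), "right": _node_to_obj(node.right)}


def _node_from_obj(obj, classes, catalogue):
    try:
        kind = obj["type"]
        if kind == "leaf":
            if obj["class"] not in classes:
                raise SchemaError(f"leaf class {obj['class']!r} not in model classes")
            return Leaf(obj["class"])
        if kind == "node":
            f = obj["feature"]
            if catalogue is not None and f not in catalogue:
                raise SchemaError(f"model references unknown feature {f!r}")
            return Node(f, float(obj["threshold"]),
                        _node_from_obj(obj["left"], classes, catalogue),
                        _node_from_obj(obj["right"], classes, catalogue))
    except KeyError as exc:
        raise SchemaError(f"malformed model node: missing {exc}") from exc
    raise SchemaError(f"unknown node type {obj.get('type')!r}")


def save_model(tree: CostedTree, path) -> None:
    obj = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "classes": list(tree.classes),
        "estimated_size_bytes": int(tree.estimated_size_bytes),
        "estimated_accuracy": None if math.isnan(tree.estimated_accuracy)
        else float(tree.estimated_accuracy),
        "root": _node_to_obj(tree.root),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def load_model(path, catalogue: FeatureCatalogue | None = None) -> CostedTree:
    """Load a serialized tree, validating features against ``catalogue``."""
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not a valid model file: {exc}") from exc
    if obj.get("format") != MODEL_FORMAT:
        raise SchemaError(f"{path}: not an {MODEL_FORMAT} file")
    if obj.get("version") != MODEL_VERSION:
        raise SchemaError(f"{path}: unsupported model version {obj.get('version')}")
    classes = tuple(obj["classes"])
    root = _node_from_obj(obj["root"], classes, catalogue)
    acc = obj.get("estimated_accuracy")
    return CostedTree(root, classes, int(obj.get("estimated_size_bytes", 0)),
                      float("nan") if acc is None else float(acc))
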
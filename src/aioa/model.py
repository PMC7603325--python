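"""statsmodels-style front end for budgeted tree induction.

:class:`BudgetedTreeModel` holds the training data, feature catalogue and
induction settings; :meth:`fit` grows a batch of candidate trees under the
byte budget and returns a :class:`BudgetedTreeResults` carrying the batch,
the selected tree, cross-validated accuracies and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FeatureCatalogue
from .trees import (
    CostedTree,
    InductionParams,
    compute_weights,
    generate_batch,
    pareto_frontier,
    save_model,
    select_tree,
    uniform_weights,
)


class BudgetedTreeModel:
    """Memory-budgeted behaviour classifier specification.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Window feature table in catalogue order.
    y : sequence of str
        Per-window behaviour labels.
    catalogue : FeatureCatalogue
        Feature byte costs; drives the inverse-cost candidate weighting.
    size_threshold : float
        Byte budget for the deployed tree (``inf`` disables filtering).
    weighting : {"cost", "uniform"}
        ``cost`` is the inverse-size weighting; ``uniform`` reproduces the
        plain random-forest candidate draw (used for comparison).
    params : InductionParams, optional
    """

    def __init__(self, X, y, catalogue: FeatureCatalogue,
                 size_threshold: float = float("inf"),
                 weighting: str = "cost",
                 params: InductionParams | None = None):
        if isinstance(X, pd.DataFrame):
            self.feature_names = [c for c in X.columns if c != "label"]
            self.X = X[self.feature_names].to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.feature_names = list(catalogue.names)[: self.X.shape[1]]
        self.y = np.asarray(y, dtype=object)
        if len(self.y) != self.X.shape[0]:
            raise ValidationError("X and y disagree in length")
        self.catalogue = catalogue
        self.size_threshold = size_threshold
        if weighting not in ("cost", "uniform"):
            raise ValidationError(f"unknown weighting {weighting!r}")
        self.weighting = weighting
        self.params = params if params is not None else InductionParams()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, catalogue: FeatureCatalogue,
                       label_col: str = "label", **kwargs) -> "BudgetedTreeModel":
        if label_col not in df.columns:
            raise ValidationError(f"missing label column {label_col!r}")
        y = df[label_col].to_numpy(dtype=object)
        X = df.drop(columns=[label_col])
        return cls(X, y, catalogue, **kwargs)

    @property
    def weights(self) -> dict[str, float]:
        if self.weighting == "cost":
            return compute_weights(self.catalogue)
        return uniform_weights(self.catalogue)

    def fit(self, n_trees: int = 20, seed: int | np.random.Generator = 0,
            cv: int = 5, attempt_cap: int | None = None,
            node_overhead_bytes: int = 0) -> "BudgetedTreeResults":
        """Grow a qualifying batch and select the deployed tree."""
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        batch = generate_batch(
            self.X, self.y, self.feature_names, self.catalogue, self.params,
            self.size_threshold, n_trees, rng,
            weights={f: self.weights[f] for f in self.feature_names},
            attempt_cap=attempt_cap, cv=cv,
            node_overhead_bytes=node_overhead_bytes,
        )
        return BudgetedTreeResults(self, batch)


@dataclass
class BudgetedTreeResults:
    """Fitted batch of budgeted trees plus the selected deployment tree."""

    model: BudgetedTreeModel
    batch: list[CostedTree]
    selected: CostedTree = field(init=False)

    def __post_init__(self):
        self.selected = select_tree(self.batch, "max_accuracy")

    @property
    def sizes_bytes(self) -> np.ndarray:
        return np.array([t.estimated_size_bytes for t in self.batch])

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([t.estimated_accuracy for t in self.batch])

    def pareto_frontier(self) -> list[CostedTree]:
        return pareto_frontier(self.batch)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(dtype=float)
        return self.selected.predict_table(np.asarray(X, dtype=float),
                                           self.model.feature_names)

    def save(self, path) -> None:
        save_model(self.selected, path)

    def batch_report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tree": np.arange(len(self.batch)),
            "size_bytes": self.sizes_bytes,
            "estimated_accuracy": self.accuracies,
            "n_nodes": [t.n_nodes() for t in self.batch],
        })

    def plot_batch(self, ax=None):
        """Scatter of footprint vs estimated accuracy, frontier highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.sizes_bytes, self.accuracies, alpha=0.6, label="batch")
        front = self.pareto_frontier()
        ax.plot([t.estimated_size_bytes for t in front],
                [t.estimated_accuracy for t in front],
                "o-", color="C1", label="Pareto frontier")
        ax.scatter([self.selected.estimated_size_bytes],
                   [self.selected.estimated_accuracy],
                   marker="*", s=180, color="C3", zorder=3, label="selected")
        ax.set_xlabel("estimated footprint (bytes)")
        ax.set_ylabel("estimated accuracy (CV)")
        ax.legend()
        return ax

    def summary(self) -> str:
        m = self.model
        sel = self.selected
        lines = [
            "Budgeted decision-tree batch",
            "=" * 60,
            f"training windows:      {m.X.shape[0]}",
            f"features:              {len(m.feature_names)}",
            f"classes:               {', '.join(sel.classes)}",
            f"weighting:             {m.weighting} (inverse byte cost)"
            if m.weighting == "cost" else
            f"weighting:             uniform",
            f"size threshold:        {m.size_threshold} bytes",
            f"trees retained:        {len(self.batch)}",
            f"footprint (bytes):     min {self.sizes_bytes.min()}, "
            f"median {int(np.median(self.sizes_bytes))}, max {self.sizes_bytes.max()}",
            f"CV accuracy:           min {self.accuracies.min():.3f}, "
            f"max {self.accuracies.max():.3f}",
            "-" * 60,
            "selected tree (max accuracy, ties to smaller size):",
            f"  footprint:           {sel.estimated_size_bytes} bytes",
            f"  CV accuracy:         {sel.estimated_accuracy:.3f}",
            f"  nodes:               {sel.n_nodes()}",
            f"  features used:       {', '.join(sorted(sel.features_used()))}",
        ]
        return "\n".join(lines)
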
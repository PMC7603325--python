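"""End-to-end in-silico experiment drivers.

These compose the library into the two headline study designs so that the
same code path serves the test-suite, the acceptance report and the CLI:

* :func:`weighting_comparison` — paired cost-weighted vs uniform-weighted
  induction over many seeds: does inverse-cost candidate weighting shrink
  tree footprints while keeping cross-validated accuracy?
* :func:`gull_deployment_comparison` — a full simulated gull deployment:
  train a budgeted tree on one synthetic trace, run the flying-armed
  foraging trigger on a held-out trace against a 15-min periodic baseline,
  and compare video-level precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import segment_windows, window_labels
from .features import acc_feature_table, default_acc_catalogue
from .model import BudgetedTreeModel
from .synthetic import make_gull_series
from .trees import InductionParams, estimate_tree_size, grow_tree, crossval_accuracy, \
    compute_weights, uniform_weights
from .triggers import BatteryModel, GullTriggerConfig, periodic_schedule, run_deployment
from .evalstats import videos_containing_target, window_metrics


def gull_training_table(series, catalogue=None):
    """Non-overlapping 1-s windows -> (X, y) in catalogue order."""
    catalogue = catalogue if catalogue is not None else default_acc_catalogue()
    windows = segment_windows(series)
    X = acc_feature_table(windows, catalogue)
    y = window_labels(windows)
    return X, y


@dataclass
class WeightingComparison:
    mean_size_cost: float
    mean_size_uniform: float
    mean_accuracy_cost: float
    mean_accuracy_uniform: float
    sizes_cost: np.ndarray
    sizes_uniform: np.ndarray

    @property
    def size_ratio(self) -> float:
        return self.mean_size_cost / self.mean_size_uniform

    @property
    def accuracy_gap(self) -> float:
        return self.mean_accuracy_cost - self.mean_accuracy_uniform


def weighting_comparison(n_seeds: int = 50, base_seed: int = 0,
                         train_s: float = 900.0, cv: int = 3,
                         catalogue=None,
                         params: InductionParams | None = None) -> WeightingComparison:
    """Paired footprint/accuracy comparison of the two candidate weightings.

    For each seed one tree is grown with inverse-cost weights and one with
    uniform weights on the same synthetic gull-like training table (same
    data, paired RNG streams), each scored by stratified cross-validation.
    """
    catalogue = catalogue if catalogue is not None else default_acc_catalogue()
    params = params if params is not None else InductionParams()
    w_cost = compute_weights(catalogue)
    w_unif = uniform_weights(catalogue)
    sizes = {"cost": [], "uniform": []}
    accs = {"cost": [], "uniform": []}
    root = np.random.default_rng(base_seed)
    for _ in range(n_seeds):
        data_seed = int(root.integers(2**31))
        series = make_gull_series(train_s, data_seed)
        X, y = gull_training_table(series, catalogue)
        for scheme, w in (("cost", w_cost), ("uniform", w_unif)):
            rng = np.random.default_rng(data_seed + (0 if scheme == "cost" else 1))
            tree = grow_tree(X, y, catalogue.names, catalogue, params, rng, w)
            sizes[scheme].append(estimate_tree_size(tree, catalogue))
            accs[scheme].append(crossval_accuracy(
                X, y, catalogue.names, catalogue, params, rng, w, cv))
    return WeightingComparison(
        float(np.mean(sizes["cost"])), float(np.mean(sizes["uniform"])),
        float(np.mean(accs["cost"])), float(np.mean(accs["uniform"])),
        np.array(sizes["cost"]), np.array(sizes["uniform"]),
    )


@dataclass
class DeploymentComparison:
    aioa_precision: float
    aioa_videos: int
    aioa_target_videos: int
    periodic_precision: float
    periodic_videos: int
    periodic_target_videos: int
    window_precision: float
    window_recall: float
    window_f: float


def gull_deployment_comparison(seed: int, train_s: float = 1200.0,
                               test_s: float = 7200.0,
                               size_threshold: float = 1000.0,
                               n_trees: int = 6,
                               periodic_interval_s: float = 900.0,
                               catalogue=None) -> DeploymentComparison:
    """One simulated gull deployment: behaviour-triggered vs periodic camera.

    Trains a budgeted tree (default: the 1000-byte threshold) on one
    synthetic trace, classifies a held-out trace window by window, and runs
    the gull trigger machine (5 flying windows to arm, foraging fires,
    10 stationary windows disarm, 60-s videos, 3-s start-up delay) against
    a 15-min periodic baseline on the identical labelled stream.  Video
    precision counts a video as a hit when it overlaps at least one
    foraging-labelled second.
    """
    catalogue = catalogue if catalogue is not None else default_acc_catalogue()
    train = make_gull_series(train_s, seed * 2 + 1)
    test = make_gull_series(test_s, seed * 2 + 2)
    X, y = gull_training_table(train, catalogue)
    model = BudgetedTreeModel(X, y, catalogue, size_threshold=size_threshold)
    res = model.fit(n_trees=n_trees, seed=seed, cv=3)
    Xt, yt = gull_training_table(test, catalogue)
    preds = res.selected.predict_table(Xt, catalogue.names)

    trigger = GullTriggerConfig()
    battery = BatteryModel()
    log = run_deployment(preds, trigger, battery, truth=yt)
    a_hit, a_tot = videos_containing_target(log, "foraging")
    wm = window_metrics(log, target="foraging")

    schedule = periodic_schedule(periodic_interval_s, trigger.video_duration_s,
                                 len(yt) * 1.0)
    plog = run_deployment(preds, None, battery, truth=yt, periodic=schedule)
    p_hit, p_tot = videos_containing_target(plog, "foraging")

    return DeploymentComparison(
        aioa_precision=a_hit / a_tot if a_tot else 0.0,
        aioa_videos=a_tot, aioa_target_videos=a_hit,
        periodic_precision=p_hit / p_tot if p_tot else 0.0,
        periodic_videos=p_tot, periodic_target_videos=p_hit,
        window_precision=wm.precision, window_recall=wm.recall,
        window_f=wm.f_measure,
    )


def deployment_win_count(n_seeds: int = 20, base_seed: int = 0,
                         **kwargs) -> tuple[int, list[DeploymentComparison]]:
    """How often AIoA triggering beats the periodic baseline on precision."""
    results = [gull_deployment_comparison(base_seed * 1000 + k, **kwargs)
               for k in range(n_seeds)]
    wins = sum(r.aioa_precision > r.periodic_precision for r in results)
    return wins, results
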
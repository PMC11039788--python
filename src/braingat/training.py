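"""Training loop, stratified cross-validation, metrics and ROI importance.

The classifier is trained with binary cross-entropy on the sigmoid output
using Adam; L2 weight decay is applied to the GAT-layer parameters only.
Cross-validation is stratified and seeded, and — crucially — the shared
adjacency is rebuilt inside every fold from that fold's *training* subjects
only, so no test-subject correlation structure (nor any test label) can leak
into the graphs a fold is evaluated on.

Reported metrics are accuracy, sensitivity (recall of the positive class,
label 1) and specificity, computed both per fold and from the confusion
counts pooled across folds.  ROI importance is the frequency with which the
first pooling layer retains each ROI across all test-subject evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam, bce_with_logits
from .connectivity import (FCMatrix, build_adjacency, build_graphs,
                           DEFAULT_THRESHOLD)
from .features import NodeFeatureMatrix
from .gat import GatClassifier, ModelConfig

__all__ = ["TrainConfig", "ConfusionCounts", "Metrics", "RoiImportanceReport",
           "CVResult", "train", "cross_validate", "compute_metrics",
           "roi_importance", "confusion_from_predictions"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 30
    weight_decay: float = 1e-4
    batch_size: int = 16
    k_folds: int = 5
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def single_site(cls, **kw) -> "TrainConfig":
        """Preset for a small single-site cohort: 30 epochs, decay 1e-4, 5 folds."""
        return cls(**{"epochs": 30, "weight_decay": 1e-4, "k_folds": 5, **kw})

    @classmethod
    def multi_site(cls, **kw) -> "TrainConfig":
        """Preset for a pooled multi-site cohort: 100 epochs, decay 1e-3, 10 folds."""
        return cls(**{"epochs": 100, "weight_decay": 1e-3, "k_folds": 10, **kw})


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FN + other.FN,
                               self.TN + other.TN, self.FP + other.FP)


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "counts": asdict(self.counts),
                "undefined": list(self.undefined)}


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity from confusion counts.

    A metric with a zero denominator is reported as NaN and flagged in
    ``undefined`` rather than silently coerced to 0.
    """
    if counts.total == 0:
        raise ValueError("no evaluated subjects")
    undefined = []
    acc = (counts.TP + counts.TN) / counts.total
    if counts.TP + counts.FN > 0:
        sens = counts.TP / (counts.TP + counts.FN)
    else:
        sens = float("nan")
        undefined.append("sensitivity")
    if counts.TN + counts.FP > 0:
        spec = counts.TN / (counts.TN + counts.FP)
    else:
        spec = float("nan")
        undefined.append("specificity")
    return Metrics(accuracy=acc, sensitivity=sens, specificity=spec,
                   counts=counts, undefined=tuple(undefined))


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))))


def train(graphs, labels, model_config: ModelConfig = ModelConfig(),
          train_config: TrainConfig = TrainConfig(),
          model: GatClassifier | None = None,
          seed: int | None = None) -> tuple[GatClassifier, list[float]]:
    """Fit the classifier; returns the model and the per-epoch loss trace.

    Minibatch Adam on binary cross-entropy; weight decay is applied only to
    the GAT-layer parameters.  Fully deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=int)
    if len(graphs) != labels.size:
        raise ValueError("graphs and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    seed = train_config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    init_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    if model is None:
        model = GatClassifier(model_config, seed=init_seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    dropout_rng = np.random.default_rng(ss.spawn(1)[0])
    opt = Adam([
        {"params": model.gat_parameters(),
         "weight_decay": train_config.weight_decay},
        {"params": model.head_parameters(), "weight_decay": 0.0},
    ], lr=train_config.learning_rate)
    n = len(graphs)
    bs = min(train_config.batch_size, n)
    trace: list[float] = []
    for _ in range(train_config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, n, bs):
            idx = order[lo:lo + bs]
            if idx.size < 2:
                continue    # batch-norm statistics need at least two graphs
            batch = [graphs[i] for i in idx]
            logits, _ = model.forward_batch(batch, training=True,
                                            rng=dropout_rng)
            loss = bce_with_logits(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
            seen += idx.size
        trace.append(epoch_loss / max(seen, 1))
    return model, trace


@dataclass
class RoiImportanceReport:
    """Selection frequency of each ROI in the first pooling layer."""

    frequencies: np.ndarray          # (n_roi,), in [0, 1]
    n_evaluations: int

    def ranked(self, labels: pd.DataFrame | None = None) -> pd.DataFrame:
        """Ranked table with 1-based ROI indices (descending frequency, ties
        by ascending index); optionally joins user-supplied anatomical labels
        on the ``roi_index_1based`` column."""
        n = self.frequencies.size
        df = pd.DataFrame({
            "roi_index_1based": np.arange(1, n + 1),
            "frequency": self.frequencies,
        })
        df = df.sort_values(["frequency", "roi_index_1based"],
                            ascending=[False, True], kind="stable")
        df["rank"] = np.arange(1, n + 1)
        if labels is not None:
            df = df.merge(labels, on="roi_index_1based", how="left")
        return df.reset_index(drop=True)


def roi_importance(selections: list[np.ndarray], n_roi: int) -> RoiImportanceReport:
    """Frequency per ROI given the pool-1 selections of each evaluation."""
    counts = np.zeros(n_roi)
    for sel in selections:
        counts[np.asarray(sel, dtype=int)] += 1
    n_eval = len(selections)
    return RoiImportanceReport(frequencies=counts / max(n_eval, 1),
                               n_evaluations=n_eval)


@dataclass
class CVResult:
    aggregate: Metrics                    # from pooled confusion counts
    per_fold: list[Metrics]
    importance: RoiImportanceReport
    fold_assignment: np.ndarray           # test-fold index per subject
    loss_traces: list[list[float]]
    config: dict

    def metrics_dict(self) -> dict:
        return {
            "aggregate": self.aggregate.as_dict(),
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean_fold_accuracy": float(np.mean(
                [m.accuracy for m in self.per_fold])),
            "config": self.config,
        }


def cross_validate(features: list[NodeFeatureMatrix], fcs: list[FCMatrix],
                   labels, model_config: ModelConfig = ModelConfig(),
                   train_config: TrainConfig = TrainConfig(),
                   threshold: float = DEFAULT_THRESHOLD,
                   adjacency_mode: str = "mean") -> CVResult:
    """Stratified k-fold cross-validation with per-fold adjacency rebuild.

    Inside every fold the averaged-FC adjacency is computed from the training
    subjects alone and shared by that fold's training *and* test graphs
    (``adjacency_mode="group"`` instead gives each subject its own class
    average — the literal but label-leaking variant, kept for comparison).
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if not (len(features) == len(fcs) == n):
        raise ValueError("features, fcs and labels differ in length")
    k = train_config.k_folds
    min_class = min(np.sum(labels == 0), np.sum(labels == 1))
    if k > min_class:
        raise ValueError(
            f"k_folds={k} exceeds the {min_class} subjects of the rarer class")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=train_config.seed)
    ss = np.random.SeedSequence(train_config.seed)
    fold_seeds = [int(s % (2 ** 31))
                  for s in ss.generate_state(k, dtype=np.uint64)]
    n_roi = features[0].n_roi
    fold_assignment = np.full(n, -1)
    per_fold: list[Metrics] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    selections: list[np.ndarray] = []
    traces: list[list[float]] = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(n), labels)):
        fold_assignment[te_idx] = fold
        tr_fcs = [fcs[i] for i in tr_idx]
        tr_labels = labels[tr_idx]
        adj = build_adjacency(tr_fcs, tr_labels, threshold, adjacency_mode)
        if adjacency_mode == "group":
            adj0, adj1 = adj
            make = lambda i: build_graphs(
                [features[i]], adj1 if labels[i] == 1 else adj0,
                [labels[i]], self_loops=model_config.self_loops)[0]
        else:
            make = lambda i: build_graphs(
                [features[i]], adj, [labels[i]],
                self_loops=model_config.self_loops)[0]
        tr_graphs = [make(i) for i in tr_idx]
        te_graphs = [make(i) for i in te_idx]
        model, trace = train(tr_graphs, tr_labels, model_config, train_config,
                             seed=fold_seeds[fold])
        traces.append(trace)
        probs = model.predict_proba(te_graphs)
        preds = (probs >= train_config.decision_threshold).astype(int)
        counts = confusion_from_predictions(labels[te_idx], preds)
        per_fold.append(compute_metrics(counts))
        pooled = pooled + counts
        for g in te_graphs:
            selections.append(model.pool1_selected(g))
    report = roi_importance(selections, n_roi)
    config = {"model": asdict(model_config), "train": asdict(train_config),
              "threshold": threshold, "adjacency_mode": adjacency_mode}
    return CVResult(aggregate=compute_metrics(pooled), per_fold=per_fold,
                    importance=report, fold_assignment=fold_assignment,
                    loss_traces=traces, config=config)
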
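"""Functional-connectivity adjacency construction.

Per-subject FC is the Pearson correlation matrix of the ROI time series.
To damp multi-site heterogeneity the per-class FC matrices are averaged and
the average is thresholded: entries below the threshold (including all
negative correlations) are zeroed, entries at or above it are preserved with
their correlation value.  The surviving entry pattern defines one shared edge
set used by every subject's graph; per-subject information enters through the
node features only.

Because a subject's own class average would leak the label into its test-time
graph, the default adjacency is the element-wise mean of the two class
averages computed on training subjects; the literal per-class variant is
available for comparison via ``mode="group"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import BoldTimeSeries
from .features import NodeFeatureMatrix

__all__ = ["FCMatrix", "AdjacencyMatrix", "BrainGraph", "pearson_fc",
           "group_average_fc", "threshold_fc", "build_adjacency",
           "build_graphs", "edges_from_adjacency", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.4


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Thresholded averaged FC; entries are 0 or >= threshold."""

    values: np.ndarray
    threshold: float

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BrainGraph:
    """One subject's graph: node features + shared undirected edge set."""

    node_features: NodeFeatureMatrix
    edges: np.ndarray            # (n_edges, 2) undirected pairs, i < j
    label: int | None
    subject_id: str
    self_loops: bool = True

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        n = self.node_features.n_roi
        if e.size and (e.min() < 0 or e.max() >= n):
            raise ValueError("edge endpoint out of range")
        if e.size:
            lo = np.minimum(e[:, 0], e[:, 1])
            hi = np.maximum(e[:, 0], e[:, 1])
            if np.any(lo == hi):
                raise ValueError("explicit self-loop in undirected edge list")
            canon = np.unique(np.stack([lo, hi], axis=1), axis=0)
            if canon.shape[0] != e.shape[0]:
                raise ValueError("duplicate undirected edges")
            e = canon
        object.__setattr__(self, "edges", e)

    @property
    def n_nodes(self) -> int:
        return self.node_features.n_roi

    def directed_edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(target, source) arrays: both directions of every undirected edge
        plus one self-loop per node when enabled."""
        tgt = [self.edges[:, 0], self.edges[:, 1]]
        src = [self.edges[:, 1], self.edges[:, 0]]
        if self.self_loops:
            loop = np.arange(self.n_nodes, dtype=np.intp)
            tgt.append(loop)
            src.append(loop)
        return np.concatenate(tgt), np.concatenate(src)


def pearson_fc(ts: BoldTimeSeries) -> FCMatrix:
    """Pearson correlation between every pair of ROI time courses."""
    x = ts.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"subject {ts.subject_id}: ROI column(s) {bad.tolist()} have zero "
            "variance; Pearson correlation is undefined")
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(values=corr, subject_id=ts.subject_id)


def group_average_fc(fcs: list[FCMatrix], labels) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean FC per class: ``(avg_group0, avg_group1)``."""
    labels = np.asarray(labels)
    if len(fcs) != labels.size:
        raise ValueError("fcs and labels differ in length")
    out = []
    for g in (0, 1):
        idx = np.flatnonzero(labels == g)
        if idx.size == 0:
            raise ValueError(f"group {g} is empty; cannot average")
        out.append(np.mean([fcs[i].values for i in idx], axis=0))
    return out[0], out[1]


def threshold_fc(avg_fc: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> AdjacencyMatrix:
    """Zero every entry strictly below ``threshold`` (signed rule: negative
    correlations are always removed); entries at the boundary are kept."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    vals = np.asarray(avg_fc, dtype=np.float64)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("averaged FC must be square")
    kept = np.where(vals >= threshold, vals, 0.0)
    return AdjacencyMatrix(values=kept, threshold=float(threshold))


def build_adjacency(fcs: list[FCMatrix], labels,
                    threshold: float = DEFAULT_THRESHOLD,
                    mode: str = "mean") -> AdjacencyMatrix | tuple[AdjacencyMatrix, AdjacencyMatrix]:
    """Averaged-and-thresholded adjacency from (training) subjects.

    ``mode="mean"`` (default, leakage-safe): threshold the mean of the two
    class averages and return one shared adjacency.  ``mode="group"``:
    threshold each class average separately and return the pair
    ``(adj_group0, adj_group1)``.
    """
    avg0, avg1 = group_average_fc(fcs, labels)
    if mode == "mean":
        return threshold_fc((avg0 + avg1) / 2.0, threshold)
    if mode == "group":
        return threshold_fc(avg0, threshold), threshold_fc(avg1, threshold)
    raise ValueError(f"unknown adjacency mode {mode!r}")


def edges_from_adjacency(adj: AdjacencyMatrix) -> np.ndarray:
    """Undirected off-diagonal edge pairs (i < j) of the surviving entries."""
    vals = adj.values
    iu = np.triu_indices(vals.shape[0], k=1)
    mask = vals[iu] != 0
    return np.stack([iu[0][mask], iu[1][mask]], axis=1).astype(np.intp)


def build_graphs(features: list[NodeFeatureMatrix], adjacency: AdjacencyMatrix,
                 labels, self_loops: bool = True) -> list[BrainGraph]:
    """Assemble one graph per subject over the shared edge set."""
    labels = list(labels)
    if len(features) != len(labels):
        raise ValueError("features and labels differ in length")
    edges = edges_from_adjacency(adjacency)
    graphs = []
    for feat, lab in zip(features, labels):
        if feat.n_roi != adjacency.n_roi:
            raise ValueError(
                f"subject {feat.subject_id}: {feat.n_roi} ROIs but adjacency "
                f"has {adjacency.n_roi}")
        graphs.append(BrainGraph(node_features=feat, edges=edges,
                                 label=lab, subject_id=feat.subject_id,
                                 self_loops=self_loops))
    return graphs
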
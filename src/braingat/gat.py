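"""Graph-attention classifier with attention-score top-K pooling.

Architecture (two blocks, then a dense head):

    H0 (N x 16) --GAT1--> H1 (N x 32) --pool1--> H1' (ceil(0.2 N) x 32)
    Z1 = GMP(H1') || GAP(H1')                       (length 64)
    H1' --GAT2--> H2 --pool2--> H2'
    Z2 = GMP(H2') || GAP(H2')                       (length 64)
    Z3 = Z1 + Z2  -> BatchNorm -> Linear(64,32) -> ReLU -> Dropout
                  -> Linear(32,1) -> sigmoid

The GAT layer computes, per attention head k, softmax-normalised coefficients

    alpha_ij^k = softmax_j( exp-score  a_k . [W_k h_i || W_k h_j] ),
    j in Neighbors(i),

averages the coefficients over heads, and aggregates neighbours through one
shared weight matrix: ``h_i' = ReLU( sum_j alpha_ij W h_j )``.  There is no
leaky-rectified score by default (a flag restores the common convention), and
the heads parameterise only the attention, not the feature transform —
``multihead_output`` switches to the usual concat/average variants for
comparison.

Top-K pooling scores node i by the total averaged attention mass on the
directed edges incident to i (each self-loop is a single edge, counted once):
its own softmax row (which always sums to 1) plus the attention it receives
from its neighbours.  Under uniform attention this reduces to a degree
centrality, so hubs are preferentially retained; the sum over all nodes is
exposed as a normalisation diagnostic.  The top ``ceil(ratio * N)`` nodes are
kept (ties broken by ascending index) and the subgraph they induce is passed
on, with original node indices recorded so pooled selections remain
interpretable as ROI identities.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, gather, segment_sum, stack
from .connectivity import BrainGraph

__all__ = ["ModelConfig", "GatLayerParams", "AttentionCoefficients",
           "PoolingResult", "attention_coefficients", "gat_forward",
           "topk_pool", "readout", "GatClassifier",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    d_in: int = 16
    d_hidden: int = 32
    n_heads: int = 4
    pool_ratio: float = 0.2
    dropout: float = 0.5
    leaky_attention: bool = False
    self_loops: bool = True
    multihead_output: str = "shared_w"   # shared_w | average | concat
    readout_prepool: bool = False
    d_head_hidden: int = 32              # width of the dense head's hidden layer

    def __post_init__(self):
        if not 0.0 < self.pool_ratio <= 1.0:
            raise ValueError("pool_ratio must lie in (0, 1]")
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.multihead_output not in ("shared_w", "average", "concat"):
            raise ValueError("multihead_output must be shared_w|average|concat")
        if self.multihead_output == "concat" and self.d_hidden % self.n_heads:
            raise ValueError("concat heads require d_hidden divisible by n_heads")


@dataclass
class GatLayerParams:
    """Per-head attention parameters plus the shared output transform."""

    W_heads: list[Tensor]    # n_heads matrices, each (d_head, d_in)
    a_heads: list[Tensor]    # n_heads vectors, each (2 * d_head,)
    W_shared: Tensor         # (d_out, d_in)

    def parameters(self) -> list[Tensor]:
        return [*self.W_heads, *self.a_heads, self.W_shared]


@dataclass
class AttentionCoefficients:
    """Head-averaged (and per-head) attention on directed pairs (i <- j)."""

    alpha: Tensor                  # (E,) head average
    per_head: list[Tensor]         # n_heads tensors of shape (E,)
    edge_index: tuple[np.ndarray, np.ndarray]   # (target, source)

    def as_dict(self) -> dict[tuple[int, int], float]:
        tgt, src = self.edge_index
        return {(int(i), int(j)): float(a)
                for i, j, a in zip(tgt, src, self.alpha.data)}


@dataclass
class PoolingResult:
    selected_indices: np.ndarray    # in the pooled graph's parent indexing
    node_scores: np.ndarray         # score per parent node
    sub_features: Tensor            # (K, d)
    sub_edge_index: tuple[np.ndarray, np.ndarray]
    global_attention: float         # sum of all node scores (diagnostic)

    @property
    def normalized_scores(self) -> np.ndarray:
        return self.node_scores / self.global_attention


def _xavier(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_gat_layer(rng: np.random.Generator, d_in: int, d_out: int,
                   n_heads: int, multihead_output: str = "shared_w") -> GatLayerParams:
    d_head = d_out // n_heads if multihead_output == "concat" else d_out
    W_heads = [Tensor(_xavier(rng, (d_head, d_in)), requires_grad=True)
               for _ in range(n_heads)]
    a_heads = [Tensor(_xavier(rng, (2 * d_head,)), requires_grad=True)
               for _ in range(n_heads)]
    W_shared = Tensor(_xavier(rng, (d_out, d_in)), requires_grad=True)
    return GatLayerParams(W_heads=W_heads, a_heads=a_heads, W_shared=W_shared)


def _check_coverage(tgt: np.ndarray, n_nodes: int) -> None:
    indeg = np.bincount(tgt, minlength=n_nodes)
    lonely = np.flatnonzero(indeg == 0)
    if lonely.size:
        raise ValueError(
            f"node(s) {lonely.tolist()} have no neighbours; enable self-loops "
            "so every node has a nonempty attention neighbourhood")


def attention_coefficients(H: Tensor | np.ndarray,
                           edge_index: tuple[np.ndarray, np.ndarray],
                           params: GatLayerParams,
                           leaky: bool = False) -> AttentionCoefficients:
    """Softmax attention per head over each node's neighbourhood, then the
    head average.  ``edge_index = (target, source)`` lists directed pairs
    (i <- j); the softmax for node i runs over all pairs with target i."""
    if not isinstance(H, Tensor):
        H = Tensor(H)
    tgt, src = edge_index
    n_nodes = H.shape[0]
    _check_coverage(tgt, n_nodes)
    per_head: list[Tensor] = []
    for Wk, a_k in zip(params.W_heads, params.a_heads):
        Wh = H @ _transpose(Wk)                       # (N, d_head)
        d = Wh.shape[1]
        s_i = Wh @ _slice_vec(a_k, 0, d)              # score part from target
        s_j = Wh @ _slice_vec(a_k, d, 2 * d)          # score part from source
        e = gather(s_i, tgt) + gather(s_j, src)
        if leaky:
            e = e.leaky_relu(0.2)
        # subtract the per-neighbourhood max (a data constant) for stability
        shift = np.full(n_nodes, -np.inf)
        np.maximum.at(shift, tgt, e.data)
        e = e + Tensor(-shift[tgt])
        ex = e.exp()
        denom = segment_sum(ex, tgt, n_nodes)
        per_head.append(ex / gather(denom, tgt))
    alpha = per_head[0]
    for a in per_head[1:]:
        alpha = alpha + a
    alpha = alpha * (1.0 / len(per_head))
    return AttentionCoefficients(alpha=alpha, per_head=per_head,
                                 edge_index=(tgt, src))


def _transpose(t: Tensor) -> Tensor:
    return t.reshape(t.shape) if t.data.ndim == 1 else _T(t)


def _T(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, parents=(t,))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g.T)
    out._backward = bw
    return out


def _slice_vec(t: Tensor, lo: int, hi: int) -> Tensor:
    out = Tensor(t.data[lo:hi], parents=(t,))

    def bw(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[lo:hi] = g
            t._accumulate(full)
    out._backward = bw
    return out


def gat_forward(H: Tensor | np.ndarray,
                edge_index: tuple[np.ndarray, np.ndarray],
                params: GatLayerParams,
                alpha: AttentionCoefficients,
                multihead_output: str = "shared_w") -> Tensor:
    """Aggregate neighbours with the attention weights and rectify.

    Default (``shared_w``): one shared matrix W transforms features and the
    head-averaged alpha weights the sum.  ``average``/``concat`` instead use
    each head's own W_k with its own alpha, combining head outputs by mean or
    concatenation.
    """
    if not isinstance(H, Tensor):
        H = Tensor(H)
    tgt, src = alpha.edge_index
    n_nodes = H.shape[0]
    if multihead_output == "shared_w":
        WH = H @ _T(params.W_shared)
        msg = gather(WH, src) * alpha.alpha.reshape(-1, 1)
        return segment_sum(msg, tgt, n_nodes).relu()
    outs = []
    for Wk, a_k_alpha in zip(params.W_heads, alpha.per_head):
        WH = H @ _T(Wk)
        msg = gather(WH, src) * a_k_alpha.reshape(-1, 1)
        outs.append(segment_sum(msg, tgt, n_nodes))
    if multihead_output == "average":
        agg = outs[0]
        for o in outs[1:]:
            agg = agg + o
        return (agg * (1.0 / len(outs))).relu()
    return concat(outs, axis=1).relu()     # concat


def node_attention_scores(alpha: AttentionCoefficients, n_nodes: int) -> np.ndarray:
    """Total attention mass on the directed edges incident to each node.

    Each directed pair (i <- j) contributes its coefficient to both endpoints;
    a self-loop is one edge and is counted once.  The row part contributes a
    constant 1 per node (softmax normalisation), so ranking is driven by the
    attention a node receives from its neighbours.
    """
    tgt, src = alpha.edge_index
    a = alpha.alpha.data
    scores = np.zeros(n_nodes)
    np.add.at(scores, tgt, a)
    np.add.at(scores, src, a)
    loop = tgt == src
    np.add.at(scores, tgt[loop], -a[loop])
    return scores


def topk_pool(H: Tensor | np.ndarray,
              edge_index: tuple[np.ndarray, np.ndarray],
              alpha: AttentionCoefficients,
              ratio: float = 0.2) -> PoolingResult:
    """Keep the ``ceil(ratio * N)`` highest-scoring nodes and induce their
    subgraph.  Ties are broken by ascending node index; self-loops among the
    survivors are retained."""
    if not isinstance(H, Tensor):
        H = Tensor(H)
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must lie in (0, 1]")
    n_nodes = H.shape[0]
    if n_nodes == 0:
        raise ValueError("cannot pool an empty graph")
    scores = node_attention_scores(alpha, n_nodes)
    k = max(1, math.ceil(ratio * n_nodes))
    order = np.lexsort((np.arange(n_nodes), -scores))
    selected = order[:k]
    sub_features = gather(H, selected)
    new_id = np.full(n_nodes, -1, dtype=np.intp)
    new_id[selected] = np.arange(k)
    tgt, src = edge_index
    keep = (new_id[tgt] >= 0) & (new_id[src] >= 0)
    sub_edges = (new_id[tgt[keep]], new_id[src[keep]])
    return PoolingResult(selected_indices=selected, node_scores=scores,
                         sub_features=sub_features, sub_edge_index=sub_edges,
                         global_attention=float(scores.sum()))


def readout(H: Tensor | np.ndarray) -> Tensor:
    """Multi-scale graph readout: per-feature max over nodes concatenated
    with the per-feature mean over nodes (length 2 d)."""
    if not isinstance(H, Tensor):
        H = Tensor(H)
    if H.shape[0] == 0:
        raise ValueError("readout of an empty node set")
    return concat([H.max(axis=0), H.mean(axis=0)], axis=0)


class GatClassifier:
    """Two GAT + top-K-pooling blocks, multi-scale readout, sigmoid head."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        c = config
        self.gat1 = init_gat_layer(rng, c.d_in, c.d_hidden, c.n_heads,
                                   c.multihead_output)
        self.gat2 = init_gat_layer(rng, c.d_hidden, c.d_hidden, c.n_heads,
                                   c.multihead_output)
        d_read = 2 * c.d_hidden
        # dense head: BatchNorm(2d) -> Linear -> ReLU -> Dropout -> Linear
        self.bn_gamma = Tensor(np.ones(d_read), requires_grad=True)
        self.bn_beta = Tensor(np.zeros(d_read), requires_grad=True)
        self.bn_mean = np.zeros(d_read)       # running buffers (not trained)
        self.bn_var = np.ones(d_read)
        self.bn_momentum = 0.1
        self.bn_eps = 1e-5
        self.fc1_W = Tensor(_xavier(rng, (c.d_head_hidden, d_read)),
                            requires_grad=True)
        self.fc1_b = Tensor(np.zeros(c.d_head_hidden), requires_grad=True)
        self.fc2_W = Tensor(_xavier(rng, (1, c.d_head_hidden)),
                            requires_grad=True)
        self.fc2_b = Tensor(np.zeros(1), requires_grad=True)

    # -- parameter groups (weight decay is scoped to the GAT layers) -----

    def gat_parameters(self) -> list[Tensor]:
        return self.gat1.parameters() + self.gat2.parameters()

    def head_parameters(self) -> list[Tensor]:
        return [self.bn_gamma, self.bn_beta, self.fc1_W, self.fc1_b,
                self.fc2_W, self.fc2_b]

    def parameters(self) -> list[Tensor]:
        return self.gat_parameters() + self.head_parameters()

    # -- forward ----------------------------------------------------------

    def embed(self, graph: BrainGraph) -> tuple[Tensor, PoolingResult, PoolingResult, np.ndarray]:
        """Graph -> (Z3, pool1, pool2, pool2's original node indices)."""
        c = self.config
        feats = graph.node_features.values
        if feats.shape[1] != c.d_in:
            raise ValueError(
                f"graph {graph.subject_id}: {feats.shape[1]} node features, "
                f"model expects {c.d_in}")
        H0 = Tensor(feats)
        edge_index = graph.directed_edge_index()
        att1 = attention_coefficients(H0, edge_index, self.gat1,
                                      leaky=c.leaky_attention)
        H1 = gat_forward(H0, edge_index, self.gat1, att1, c.multihead_output)
        pool1 = topk_pool(H1, edge_index, att1, c.pool_ratio)
        Z1 = readout(H1) if c.readout_prepool else readout(pool1.sub_features)
        att2 = attention_coefficients(pool1.sub_features, pool1.sub_edge_index,
                                      self.gat2, leaky=c.leaky_attention)
        H2 = gat_forward(pool1.sub_features, pool1.sub_edge_index, self.gat2,
                         att2, c.multihead_output)
        pool2 = topk_pool(H2, pool1.sub_edge_index, att2, c.pool_ratio)
        Z2 = readout(H2) if c.readout_prepool else readout(pool2.sub_features)
        if Z1.shape != Z2.shape:
            raise ValueError("multi-scale readouts differ in length; "
                             "Z3 = Z1 + Z2 requires equal GAT widths")
        pool2_original = pool1.selected_indices[pool2.selected_indices]
        return Z1 + Z2, pool1, pool2, pool2_original

    def head(self, Z: Tensor, training: bool = False,
             rng: np.random.Generator | None = None) -> Tensor:
        """Dense head on a batch of readout vectors (B x 2d) -> logits (B,)."""
        c = self.config
        if training:
            mu = Z.mean(axis=0, keepdims=True)
            var = (Z - mu).square().mean(axis=0, keepdims=True)
            self.bn_mean = ((1 - self.bn_momentum) * self.bn_mean
                            + self.bn_momentum * mu.data.ravel())
            n = Z.shape[0]
            unbias = n / max(n - 1, 1)
            self.bn_var = ((1 - self.bn_momentum) * self.bn_var
                           + self.bn_momentum * var.data.ravel() * unbias)
            Zn = (Z - mu) / (var + self.bn_eps).sqrt()
        else:
            Zn = (Z - Tensor(self.bn_mean)) * Tensor(
                1.0 / np.sqrt(self.bn_var + self.bn_eps))
        Zn = Zn * self.bn_gamma + self.bn_beta
        X = (Zn @ _T(self.fc1_W) + self.fc1_b).relu()
        if training and c.dropout > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            mask = (rng.random(X.shape) >= c.dropout) / (1.0 - c.dropout)
            X = X * Tensor(mask)
        logits = X @ _T(self.fc2_W) + self.fc2_b
        return logits.reshape(-1)

    def forward_batch(self, graphs: list[BrainGraph], training: bool = False,
                      rng: np.random.Generator | None = None
                      ) -> tuple[Tensor, list[PoolingResult]]:
        embeds, pools = [], []
        for g in graphs:
            z3, pool1, _, _ = self.embed(g)
            embeds.append(z3)
            pools.append(pool1)
        Z = stack(embeds, axis=0)
        return self.head(Z, training=training, rng=rng), pools

    def predict_proba(self, graphs: list[BrainGraph]) -> np.ndarray:
        logits, _ = self.forward_batch(graphs, training=False)
        return 1.0 / (1.0 + np.exp(-logits.data))

    def model_forward(self, graph: BrainGraph) -> float:
        """Single-graph evaluation-mode class probability in (0, 1)."""
        return float(self.predict_proba([graph])[0])

    def pool1_selected(self, graph: BrainGraph) -> np.ndarray:
        """Original ROI indices retained by the first pooling layer."""
        _, pool1, _, _ = self.embed(graph)
        return np.sort(pool1.selected_indices)

    # -- checkpoint state -------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs: dict[str, np.ndarray] = {}
        for li, layer in enumerate((self.gat1, self.gat2), start=1):
            for k, (Wk, a_k) in enumerate(zip(layer.W_heads, layer.a_heads)):
                arrs[f"gat{li}.W_head{k}"] = Wk.data
                arrs[f"gat{li}.a_head{k}"] = a_k.data
            arrs[f"gat{li}.W_shared"] = layer.W_shared.data
        arrs["bn.gamma"] = self.bn_gamma.data
        arrs["bn.beta"] = self.bn_beta.data
        arrs["bn.running_mean"] = self.bn_mean
        arrs["bn.running_var"] = self.bn_var
        arrs["fc1.W"] = self.fc1_W.data
        arrs["fc1.b"] = self.fc1_b.data
        arrs["fc2.W"] = self.fc2_W.data
        arrs["fc2.b"] = self.fc2_b.data
        return arrs

    def load_state_arrays(self, arrs: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(arrs):
            raise ValueError("checkpoint parameter names do not match model")
        for li, layer in enumerate((self.gat1, self.gat2), start=1):
            for k in range(len(layer.W_heads)):
                layer.W_heads[k].data = np.array(arrs[f"gat{li}.W_head{k}"])
                layer.a_heads[k].data = np.array(arrs[f"gat{li}.a_head{k}"])
            layer.W_shared.data = np.array(arrs[f"gat{li}.W_shared"])
        self.bn_gamma.data = np.array(arrs["bn.gamma"])
        self.bn_beta.data = np.array(arrs["bn.beta"])
        self.bn_mean = np.array(arrs["bn.running_mean"])
        self.bn_var = np.array(arrs["bn.running_var"])
        self.fc1_W.data = np.array(arrs["fc1.W"])
        self.fc1_b.data = np.array(arrs["fc1.b"])
        self.fc2_W.data = np.array(arrs["fc2.W"])
        self.fc2_b.data = np.array(arrs["fc2.b"])


# -- checkpoint file format ------------------------------------------------
# magic line, 16-digit header length, JSON header (config + array manifest +
# payload sha256), then the raw little-endian float64 array payload.

_MAGIC = b"BRAINGAT-CKPT-1\n"


def save_checkpoint(model: GatClassifier, path: str | Path) -> None:
    arrs = model.state_arrays()
    manifest, payload = [], b""
    for name, arr in arrs.items():
        raw = np.ascontiguousarray(arr, dtype="<f8").tobytes()
        manifest.append({"name": name, "shape": list(arr.shape),
                         "offset": len(payload), "nbytes": len(raw)})
        payload += raw
    header = json.dumps({
        "config": asdict(model.config),
        "arrays": manifest,
        "sha256": hashlib.sha256(payload).hexdigest(),
    }).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(f"{len(header):016d}".encode())
        fh.write(header)
        fh.write(payload)


def load_checkpoint(path: str | Path) -> GatClassifier:
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path}: not a braingat checkpoint")
        try:
            hlen = int(fh.read(16))
            header = json.loads(fh.read(hlen))
        except (ValueError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: corrupt checkpoint header") from exc
        payload = fh.read()
    if hashlib.sha256(payload).hexdigest() != header.get("sha256"):
        raise ValueError(f"{path}: checkpoint payload hash mismatch")
    model = GatClassifier(ModelConfig(**header["config"]))
    arrs = {}
    for m in header["arrays"]:
        raw = payload[m["offset"]:m["offset"] + m["nbytes"]]
        arrs[m["name"]] = np.frombuffer(raw, dtype="<f8").reshape(m["shape"]).copy()
    model.load_state_arrays(arrs)
    return model
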
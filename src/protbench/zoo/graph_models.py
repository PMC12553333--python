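"""Structure-based architectures over peptide molecular graphs.

All seven models share the disjoint-union batching of
:mod:`protbench.zoo.batches` and a permutation-invariant readout; they
differ in the propagation rule:

* GCN — symmetric-normalized propagation with self-loops,
  ``H' = sigma(D~^-1/2 A~ D~^-1/2 H W)``.
* GAT — attention coefficients over N(i) ∪ {i}.
* MPNN — edge-conditioned messages with a learned update map.
* NeuralFP — frozen GCN-derived fingerprint + trainable 3-layer MLP.
* AttentiveFP — edge-aware attention layers with a gated attentive readout.
* PAGTN — attention over node pairs within 3 hops, with summed bond
  features along a shortest path as the pair feature.
* Graphormer — dense per-graph self-attention with degree (centrality)
  embeddings and shortest-path spatial bias capped at distance 5.

Graph models run in float64: they are small, and exact permutation
invariance of the readouts is part of their contract.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ..core import PairRecord, Record, TaskSpec
from ..errors import EmptyGraph
from ..graph_features import MolecularGraph
from ..nn import BatchNorm1d, Dropout, LayerNorm, Linear, Module, ModuleList
from ..nn import tensor as T
from ..nn.tensor import Tensor
from .base import MLPHead, PredictorModel, activation_fn
from .batches import GraphBatch, ModelBatch, batch_graphs, peptide_graph_cached

DTYPE = np.float64
ATTN_LEAK = 0.2  # slope of the LeakyReLU used inside attention scores


# -- cached per-graph geometry -------------------------------------------

def _graph_distances(g: MolecularGraph) -> Tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distances and predecessors (cached on the graph)."""
    cached = getattr(g, "_sp_cache", None)
    if cached is not None:
        return cached
    n = g.n_atoms
    if g.n_edges:
        e = np.asarray(g.edges)
        adj = csr_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    else:
        adj = csr_matrix((n, n))
    dist, pred = shortest_path(adj, directed=False, unweighted=True,
                               return_predecessors=True)
    g._sp_cache = (dist, pred)
    return dist, pred


def _pagtn_pairs(g: MolecularGraph, max_hops: int) -> Tuple[np.ndarray, ...]:
    """Ordered node pairs within ``max_hops`` (self included) plus the sum
    of bond features along one shortest path (cached)."""
    cached = getattr(g, "_pagtn_cache", None)
    if cached is not None and cached[0] == max_hops:
        return cached[1]
    dist, pred = _graph_distances(g)
    bond_lut = {}
    for (u, v), f in zip(g.edges, g.edge_features):
        bond_lut[(u, v)] = f
        bond_lut[(v, u)] = f
    srcs, dsts, feats = [], [], []
    n = g.n_atoms
    d_edge = g.edge_features.shape[1] if g.n_edges else 3
    for v in range(n):
        for u in range(n):
            d = dist[u, v]
            if not np.isfinite(d) or d > max_hops:
                continue
            path_feat = np.zeros(d_edge, dtype=DTYPE)
            cur = v
            while cur != u:
                prev = pred[u, cur]
                path_feat += bond_lut[(prev, cur)]
                cur = prev
            srcs.append(u)
            dsts.append(v)
            feats.append(path_feat)
    out = (np.asarray(srcs, dtype=np.int64), np.asarray(dsts, dtype=np.int64),
           np.asarray(feats, dtype=DTYPE))
    g._pagtn_cache = (max_hops, out)
    return out


# -- readouts -------------------------------------------------------------

class Readout(Module):
    """Permutation-invariant graph pooling; kind selects the flavor."""

    def __init__(self, kind: str, dim: int, rng: np.random.Generator):
        super().__init__()
        self.kind = kind
        if kind == "weighted_sum_max":
            self.gate = Linear(dim, 1, rng, DTYPE)
            self.out_dim = 2 * dim
        elif kind == "sum_max":
            self.out_dim = 2 * dim
        elif kind == "max":
            self.out_dim = dim
        elif kind == "attentive":
            self.score = Linear(dim, 1, rng, DTYPE)
            self.proj = Linear(dim, dim, rng, DTYPE)
            self.out_dim = dim
        else:
            raise ValueError(f"unknown readout {kind!r}")

    def forward(self, h: Tensor, graph_id: np.ndarray, n_graphs: int) -> Tensor:
        if self.kind == "weighted_sum_max":
            w = T.sigmoid(self.gate(h))
            s = T.segment_sum(w * h, graph_id, n_graphs)
            m = T.segment_max(h, graph_id, n_graphs)
            return T.concat([s, m], axis=-1)
        if self.kind == "sum_max":
            s = T.segment_sum(h, graph_id, n_graphs)
            m = T.segment_max(h, graph_id, n_graphs)
            return T.concat([s, m], axis=-1)
        if self.kind == "max":
            return T.segment_max(h, graph_id, n_graphs)
        # gated attentive pooling
        scores = T.reshape(self.score(h), (h.shape[0],))
        alpha = T.segment_softmax(scores, graph_id, n_graphs)
        gated = T.reshape(alpha, (h.shape[0], 1)) * T.tanh(self.proj(h))
        return T.segment_sum(gated, graph_id, n_graphs)


# -- layers ---------------------------------------------------------------

class GCNLayer(Module):
    """One symmetric-normalized propagation with self-loops."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Linear(in_dim, out_dim, rng, DTYPE).weight
        self.bias = Tensor(np.zeros(out_dim, dtype=DTYPE), requires_grad=True)

    def forward(self, h: Tensor, gb: GraphBatch) -> Tensor:
        n = gb.node_feat.shape[0]
        deg = np.bincount(gb.dst, minlength=n) + 1.0  # self-loop degree
        norm = Tensor((deg ** -0.5)[:, None].astype(DTYPE))
        hw = T.matmul(h, self.weight)
        s = hw * norm
        agg = T.segment_sum(T.take_rows(s, gb.src), gb.dst, n) + s
        return agg * norm + self.bias


class GATLayer(Module):
    """Multi-head attention aggregation over N(i) ∪ {i}."""

    def __init__(self, in_dim: int, out_dim: int, n_heads: int,
                 rng: np.random.Generator):
        super().__init__()
        assert out_dim % n_heads == 0
        self.h = n_heads
        self.dh = out_dim // n_heads
        self.w = Linear(in_dim, out_dim, rng, DTYPE)
        bound = 1.0 / np.sqrt(out_dim)
        self.attn_l = Tensor(rng.uniform(-bound, bound, (self.h, self.dh)),
                             requires_grad=True)
        self.attn_r = Tensor(rng.uniform(-bound, bound, (self.h, self.dh)),
                             requires_grad=True)

    def forward(self, h: Tensor, gb: GraphBatch) -> Tensor:
        n = gb.node_feat.shape[0]
        loop = np.arange(n, dtype=np.int64)
        src = np.concatenate([gb.src, loop])
        dst = np.concatenate([gb.dst, loop])
        hw = T.reshape(self.w(h), (n, self.h, self.dh))
        el = T.tsum(hw * self.attn_l, axis=-1)  # (n, heads)
        er = T.tsum(hw * self.attn_r, axis=-1)
        e = T.leaky_relu(T.take_rows(el, src) + T.take_rows(er, dst), ATTN_LEAK)
        alpha = T.segment_softmax(e, dst, n)  # (E, heads)
        msg = T.reshape(alpha, (len(src), self.h, 1)) * T.take_rows(hw, src)
        out = T.segment_sum(msg, dst, n)
        return T.reshape(out, (n, self.h * self.dh))


class MPNNLayer(Module):
    """Edge-conditioned message passing: m_v = sum M(h_u, e_uv); U update."""

    def __init__(self, dim: int, edge_dim: int, rng: np.random.Generator):
        super().__init__()
        self.msg = Linear(dim + edge_dim, dim, rng, DTYPE)
        self.upd = Linear(2 * dim, dim, rng, DTYPE)

    def forward(self, h: Tensor, edge_emb: Tensor, gb: GraphBatch) -> Tensor:
        n = gb.node_feat.shape[0]
        m_in = T.concat([T.take_rows(h, gb.src), edge_emb], axis=-1)
        m = T.relu(self.msg(m_in))
        agg = T.segment_sum(m, gb.dst, n)
        return T.relu(self.upd(T.concat([h, agg], axis=-1)))


class AttentiveFPLayer(Module):
    """Edge-aware attention aggregation with a linear node update."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.msg = Linear(2 * dim, dim, rng, DTYPE)
        self.score = Linear(2 * dim, 1, rng, DTYPE)
        self.upd = Linear(2 * dim, dim, rng, DTYPE)

    def forward(self, h: Tensor, edge_emb: Tensor, gb: GraphBatch) -> Tensor:
        n = gb.node_feat.shape[0]
        m = T.relu(self.msg(T.concat([T.take_rows(h, gb.src), edge_emb], -1)))
        s_in = T.concat([T.take_rows(h, gb.dst), m], axis=-1)
        s = T.reshape(T.leaky_relu(self.score(s_in), ATTN_LEAK), (len(gb.src),))
        alpha = T.segment_softmax(s, gb.dst, n)
        ctx = T.segment_sum(T.reshape(alpha, (len(gb.src), 1)) * m, gb.dst, n)
        return T.relu(self.upd(T.concat([h, ctx], axis=-1)))


class PAGTNLayer(Module):
    """Attention over path-augmented pairs (<= max_hops)."""

    def __init__(self, dim: int, edge_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = Linear(dim, dim, rng, DTYPE)
        self.wp = Linear(edge_dim, dim, rng, DTYPE)
        self.score = Linear(3 * dim, 1, rng, DTYPE)

    def forward(self, h: Tensor, pairs, n: int) -> Tensor:
        psrc, pdst, pfeat = pairs
        hw = self.w(h)
        pf = self.wp(Tensor(pfeat))
        hs, hd = T.take_rows(hw, psrc), T.take_rows(hw, pdst)
        s_in = T.concat([hs, hd, pf], axis=-1)
        s = T.reshape(T.leaky_relu(self.score(s_in), ATTN_LEAK), (len(psrc),))
        alpha = T.segment_softmax(s, pdst, n)
        msg = T.reshape(alpha, (len(psrc), 1)) * (hs + pf)
        return T.segment_sum(msg, pdst, n)


class GraphormerLayer(Module):
    """Dense per-graph self-attention with spatial and edge bias."""

    def __init__(self, dim: int, n_heads: int, max_dist: int,
                 rng: np.random.Generator, norm: str, dropout: float):
        super().__init__()
        assert dim % n_heads == 0
        self.h = n_heads
        self.dh = dim // n_heads
        self.max_dist = max_dist
        self.wq = Linear(dim, dim, rng, DTYPE)
        self.wk = Linear(dim, dim, rng, DTYPE)
        self.wv = Linear(dim, dim, rng, DTYPE)
        self.wo = Linear(dim, dim, rng, DTYPE)
        self.spatial_bias = Tensor(
            np.zeros((max_dist + 1, n_heads), dtype=DTYPE), requires_grad=True)
        self.edge_bias = Linear(3, n_heads, rng, DTYPE)
        self.ff1 = Linear(dim, 4 * dim, rng, DTYPE)
        self.ff2 = Linear(4 * dim, dim, rng, DTYPE)
        self.ln = LayerNorm(dim, dtype=DTYPE) if norm == "layer" else None
        self.drop = Dropout(dropout)

    def forward(self, h: Tensor, gb: GraphBatch) -> Tensor:
        outs = []
        for i, g in enumerate(gb.graphs):
            lo, hi = gb.node_offsets[i], gb.node_offsets[i + 1]
            n = hi - lo
            hg = h[lo:hi]
            dist, _ = _graph_distances(g)
            dcap = np.minimum(dist, self.max_dist).astype(np.int64)
            sb = T.transpose(T.take_rows(
                T.reshape(self.spatial_bias, (self.max_dist + 1, self.h)),
                dcap.ravel()).reshape((n, n, self.h)), (2, 0, 1))
            ef = np.zeros((n, n, 3), dtype=DTYPE)
            for (u, v), f in zip(g.edges, g.edge_features):
                ef[u, v] = f
                ef[v, u] = f
            eb = T.transpose(self.edge_bias(Tensor(ef)), (2, 0, 1))
            q = T.transpose(T.reshape(self.wq(hg), (n, self.h, self.dh)), (1, 0, 2))
            k = T.transpose(T.reshape(self.wk(hg), (n, self.h, self.dh)), (1, 0, 2))
            v = T.transpose(T.reshape(self.wv(hg), (n, self.h, self.dh)), (1, 0, 2))
            logits = T.matmul(q, T.transpose(k, (0, 2, 1))) * (1.0 / np.sqrt(self.dh))
            att = T.softmax(logits + sb + eb, axis=-1)
            out = T.reshape(T.transpose(T.matmul(att, v), (1, 0, 2)),
                            (n, self.h * self.dh))
            outs.append(self.wo(out))
        attn_out = T.concat(outs, axis=0) if len(outs) > 1 else outs[0]
        x = h + self.drop(T.relu(attn_out))
        x = x + self.ff2(self.drop(T.relu(self.ff1(x))))
        if self.ln is not None:
            x = self.ln(x)
        return x


# -- models ---------------------------------------------------------------

class GraphModel(PredictorModel):
    """Common prepare/forward plumbing for structure-based models."""

    def prepare(self, records: Sequence[Record]) -> ModelBatch:
        ts = self.task_spec
        if ts.arity == "pair":
            recs: List[PairRecord] = list(records)
            gb_a = batch_graphs([peptide_graph_cached(r.sequence_a) for r in recs])
            gb_b = batch_graphs([peptide_graph_cached(r.sequence_b) for r in recs])
            inputs = (gb_a, gb_b)
        else:
            recs = list(records)
            inputs = batch_graphs([peptide_graph_cached(r.sequence) for r in recs])
        if ts.is_classification:
            labels = np.asarray([r.label for r in recs], dtype=np.int64)
        else:
            labels = np.asarray([r.label for r in recs], dtype=np.float64)
        return ModelBatch(inputs=inputs, labels=labels, ids=[r.id for r in recs])

    def encode(self, gb: GraphBatch) -> Tensor:
        raise NotImplementedError

    def _pool(self, gb: GraphBatch) -> Tensor:
        if gb.n_graphs == 0 or gb.node_feat.shape[0] == 0:
            raise EmptyGraph("cannot run a graph model on an empty batch")
        return self.readout(self.encode(gb), gb.graph_id, gb.n_graphs)

    def forward(self, batch: ModelBatch) -> Tensor:
        if self.task_spec.arity == "pair":
            gb_a, gb_b = batch.inputs
            rep = T.concat([self._pool(gb_a), self._pool(gb_b)], axis=-1)
        else:
            rep = self._pool(batch.inputs)
        return self.squeeze_output(self.head(rep))

    def _make_head(self, rng: np.random.Generator) -> None:
        cfg = self.config
        head_in = self.readout.out_dim * (2 if self.task_spec.arity == "pair" else 1)
        self.head = MLPHead(head_in, cfg.hidden_dim, self.out_dim, rng,
                            cfg.activation, cfg.norm, cfg.dropout, DTYPE)


class GCNModel(GraphModel):
    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        dims = [config.node_feat_dim] + [config.hidden_dim] * config.n_layers
        self.layers = ModuleList([GCNLayer(a, b, rng)
                                  for a, b in zip(dims[:-1], dims[1:])])
        self.act = activation_fn(config.activation)
        self.readout = Readout(config.readout, config.hidden_dim, rng)
        self._make_head(rng)

    def encode(self, gb: GraphBatch) -> Tensor:
        h = Tensor(gb.node_feat.astype(DTYPE))
        for layer in self.layers:
            h = self.act(layer(h, gb))
        return h


class GATModel(GraphModel):
    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        dims = [config.node_feat_dim] + [config.hidden_dim] * config.n_layers
        self.layers = ModuleList([GATLayer(a, b, config.n_heads, rng)
                                  for a, b in zip(dims[:-1], dims[1:])])
        self.act = activation_fn(config.activation)
        self.readout = Readout(config.readout, config.hidden_dim, rng)
        self._make_head(rng)

    def encode(self, gb: GraphBatch) -> Tensor:
        h = Tensor(gb.node_feat.astype(DTYPE))
        for layer in self.layers:
            h = self.act(layer(h, gb))
        return h


class MPNNModel(GraphModel):
    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        H = config.hidden_dim
        self.node_in = Linear(config.node_feat_dim, H, rng, DTYPE)
        self.edge_in = Linear(config.edge_feat_dim, H, rng, DTYPE)
        self.layers = ModuleList([MPNNLayer(H, H, rng)
                                  for _ in range(config.n_layers)])
        self.readout = Readout(config.readout, H, rng)
        self._make_head(rng)

    def encode(self, gb: GraphBatch) -> Tensor:
        h = T.relu(self.node_in(Tensor(gb.node_feat.astype(DTYPE))))
        e = T.relu(self.edge_in(Tensor(gb.edge_feat.astype(DTYPE))))
        for layer in self.layers:
            h = layer(h, e, gb)
        return h


class NeuralFPModel(GraphModel):
    """Frozen GCN fingerprint (seeded initial pass) + trainable 3-layer MLP."""

    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        H = config.hidden_dim
        dims = [config.node_feat_dim] + [H] * config.n_layers
        self.layers = ModuleList([GCNLayer(a, b, rng)
                                  for a, b in zip(dims[:-1], dims[1:])])
        self.fp_proj = ModuleList([Linear(H, H, rng, DTYPE)
                                   for _ in range(config.n_layers)])
        for p in list(self.layers.parameters()) + list(self.fp_proj.parameters()):
            p.requires_grad = False  # fingerprint is fixed after the initial pass
        self.act = activation_fn(config.activation)
        self.readout = Readout(config.readout, H, rng)
        mlp_rng = rng
        head_in = self.readout.out_dim * (2 if task_spec.arity == "pair" else 1)
        self.mlp1 = Linear(head_in, H, mlp_rng, DTYPE)
        self.bn1 = BatchNorm1d(H, dtype=DTYPE)
        self.mlp2 = Linear(H, H, mlp_rng, DTYPE)
        self.bn2 = BatchNorm1d(H, dtype=DTYPE)
        self.mlp3 = Linear(H, self.out_dim, mlp_rng, DTYPE)
        self.drop = Dropout(config.dropout)

    def encode(self, gb: GraphBatch) -> Tensor:
        h = Tensor(gb.node_feat.astype(DTYPE))
        fp = None
        for layer, proj in zip(self.layers, self.fp_proj):
            h = self.act(layer(h, gb))
            contrib = T.softmax(proj(h), axis=-1)
            fp = contrib if fp is None else fp + contrib
        return fp

    def forward(self, batch: ModelBatch) -> Tensor:
        if self.task_spec.arity == "pair":
            gb_a, gb_b = batch.inputs
            rep = T.concat([self._pool(gb_a), self._pool(gb_b)], axis=-1)
        else:
            rep = self._pool(batch.inputs)
        h = self.bn1(T.relu(self.mlp1(rep)))
        h = self.bn2(T.relu(self.mlp2(self.drop(h))))
        return self.squeeze_output(self.mlp3(self.drop(h)))


class AttentiveFPModel(GraphModel):
    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        H = config.hidden_dim
        self.node_in = Linear(config.node_feat_dim, H, rng, DTYPE)
        self.edge_in = Linear(config.edge_feat_dim, H, rng, DTYPE)
        self.layers = ModuleList([AttentiveFPLayer(H, rng)
                                  for _ in range(config.n_layers)])
        self.readout = Readout(config.readout, H, rng)
        self._make_head(rng)

    def encode(self, gb: GraphBatch) -> Tensor:
        h = T.relu(self.node_in(Tensor(gb.node_feat.astype(DTYPE))))
        e = T.relu(self.edge_in(Tensor(gb.edge_feat.astype(DTYPE))))
        for layer in self.layers:
            h = layer(h, e, gb)
        return h


class PAGTNModel(GraphModel):
    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        H = config.hidden_dim
        self.node_in = Linear(config.node_feat_dim, H, rng, DTYPE)
        self.layers = ModuleList([PAGTNLayer(H, config.edge_feat_dim, rng)
                                  for _ in range(config.n_layers)])
        self.act = activation_fn(config.activation)
        self.max_hops = config.max_path_hops
        self.readout = Readout(config.readout, H, rng)
        self._make_head(rng)

    def encode(self, gb: GraphBatch) -> Tensor:
        n = gb.node_feat.shape[0]
        srcs, dsts, feats = [], [], []
        for i, g in enumerate(gb.graphs):
            ps, pd, pf = _pagtn_pairs(g, self.max_hops)
            off = gb.node_offsets[i]
            srcs.append(ps + off)
            dsts.append(pd + off)
            feats.append(pf)
        pairs = (np.concatenate(srcs), np.concatenate(dsts),
                 np.concatenate(feats, axis=0))
        h = self.act(self.node_in(Tensor(gb.node_feat.astype(DTYPE))))
        for layer in self.layers:
            h = self.act(layer(h, pairs, n))
        return h


class GraphormerModel(GraphModel):
    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        H = config.hidden_dim
        self.node_in = Linear(config.node_feat_dim, H, rng, DTYPE)
        self.deg_embed = Tensor(
            rng.uniform(-0.1, 0.1, (config.max_degree + 1, H)).astype(DTYPE),
            requires_grad=True)
        self.max_degree = config.max_degree
        self.layers = ModuleList([
            GraphormerLayer(H, config.n_heads, config.max_spatial_dist, rng,
                            config.norm, config.dropout)
            for _ in range(config.n_layers)
        ])
        self.readout = Readout(config.readout, H, rng)
        self._make_head(rng)

    def encode(self, gb: GraphBatch) -> Tensor:
        deg = np.bincount(gb.dst, minlength=gb.node_feat.shape[0])
        deg = np.minimum(deg, self.max_degree)
        h = self.node_in(Tensor(gb.node_feat.astype(DTYPE)))
        h = h + T.take_rows(self.deg_embed, deg)
        for layer in self.layers:
            h = layer(h, gb)
        return h
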
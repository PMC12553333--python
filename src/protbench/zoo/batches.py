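"""Prepared mini-batch containers shared by the model zoo and the trainer."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, List, Optional, Tuple

import numpy as np

from ..graph_features import MolecularGraph, sequence_to_peptide_graph


@dataclass
class ModelBatch:
    """Featurized inputs plus aligned labels for one mini-batch.

    ``inputs`` is architecture-specific; ``label_mask`` is only set for
    residue-level tasks (1 = real residue position).
    """

    inputs: Any
    labels: Optional[np.ndarray] = None
    label_mask: Optional[np.ndarray] = None
    ids: Optional[List[str]] = None


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with segment bookkeeping.

    Directed edges store both copies of every bond; ``graph_id`` maps each
    node to its source graph.  ``graphs`` keeps the per-graph objects for
    architectures that need dense per-graph work (shortest paths).
    """

    node_feat: np.ndarray      # (N, d_node)
    src: np.ndarray            # (E2,)
    dst: np.ndarray            # (E2,)
    edge_feat: np.ndarray      # (E2, d_edge)
    graph_id: np.ndarray       # (N,)
    node_offsets: np.ndarray   # (n_graphs + 1,)
    n_graphs: int
    graphs: List[MolecularGraph]


_GRAPH_CACHE: dict = {}


def peptide_graph_cached(sequence: str) -> MolecularGraph:
    g = _GRAPH_CACHE.get(sequence)
    if g is None:
        g = sequence_to_peptide_graph(sequence)
        _GRAPH_CACHE[sequence] = g
    return g


def batch_graphs(graphs: List[MolecularGraph]) -> GraphBatch:
    """Concatenate graphs into one disjoint-union batch."""
    offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
    feats, efeats, srcs, dsts, gids = [], [], [], [], []
    for i, g in enumerate(graphs):
        feats.append(g.node_features)
        s, d, eidx = g.directed_edges()
        srcs.append(s + offsets[i])
        dsts.append(d + offsets[i])
        efeats.append(g.edge_features[eidx] if g.n_edges else
                      np.zeros((0, 3), dtype=np.float64))
        gids.append(np.full(g.n_atoms, i, dtype=np.int64))
    return GraphBatch(
        node_feat=np.concatenate(feats, axis=0),
        src=np.concatenate(srcs),
        dst=np.concatenate(dsts),
        edge_feat=np.concatenate(efeats, axis=0),
        graph_id=np.concatenate(gids),
        node_offsets=offsets,
        n_graphs=len(graphs),
        graphs=graphs,
    )
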
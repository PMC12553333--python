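"""Model zoo: ten architectures plus a fixed-embedding head, with the
shipped default configuration per architecture and a uniform forward
contract (see :mod:`protbench.zoo.base`)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..core import TaskSpec
from ..errors import EmptyGraph, IncompatibleArchitecture, ShapeMismatch
from ..graph_features import MolecularGraph
from ..sequence_features import MAX_LENGTH
from .base import MLPHead, PredictorModel, output_width
from .batches import GraphBatch, ModelBatch, batch_graphs, peptide_graph_cached
from .embedding import (
    EmbeddingProvider,
    FixedEmbeddingModel,
    hashed_random_provider,
    kmer_provider,
    table_provider,
)
from .graph_models import (
    AttentiveFPModel,
    GATModel,
    GCNLayer,
    GCNModel,
    GraphModel,
    GraphormerModel,
    MPNNModel,
    NeuralFPModel,
    PAGTNModel,
    Readout,
)
from .sequence_models import CNNGRUModel, CNNModel, SequenceModel, TransformerModel

SEQUENCE_ARCHITECTURES = ("cnn", "cnn_gru", "transformer")
GRAPH_ARCHITECTURES = ("gcn", "gat", "mpnn", "neuralfp", "attentivefp",
                       "pagtn", "graphormer")
ARCHITECTURES = SEQUENCE_ARCHITECTURES + GRAPH_ARCHITECTURES + ("fixed_embedding",)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; ``default_config`` reproduces the
    shipped baseline row-for-row (learning rate 1e-4 for sequence-based,
    1e-5 for structure-based; batch 32; up to 100 epochs; dropout 0.1)."""

    architecture: str
    hidden_dim: int = 64
    n_layers: int = 3
    n_heads: Optional[int] = None
    activation: str = "relu"
    norm: str = "none"
    readout: str = ""
    dropout: float = 0.1
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    # sequence-model extras
    conv_filters: Tuple[int, ...] = (32, 64, 96)
    conv_kernels: Tuple[int, ...] = (4, 8, 12)
    max_length: int = MAX_LENGTH
    dtype: str = "float32"
    # graph-model extras
    node_feat_dim: int = 5
    edge_feat_dim: int = 3
    max_path_hops: int = 3
    max_spatial_dist: int = 5
    max_degree: int = 4

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64

    def to_dict(self) -> Dict:
        return asdict(self)

    def table_row(self) -> Dict[str, object]:
        """Human-readable defaults dump (one row of the config table)."""
        pooling = {"max_seq": "MaxPool1d", "weighted_sum_max": "Weighted Sum + Max",
                   "sum_max": "Sum + Max", "attentive": "AttentiveFPReadout",
                   "max": "MaxPooling", "": ""}[self.readout]
        norm = {"none": "", "layer": "LayerNorm", "batch": "BatchNorm"}[self.norm]
        act = {"relu": "ReLU", "leaky_relu": "LeakyReLU"}[self.activation]
        return {
            "model": self.architecture,
            "lr": self.learning_rate,
            "dropout": self.dropout,
            "activation": act,
            "n_heads": self.n_heads if self.n_heads else "",
            "n_layers": self.n_layers,
            "hidden_dim": self.hidden_dim,
            "pooling": pooling,
            "batch_size": self.batch_size,
            "n_epochs": self.max_epochs,
            "norm": norm,
        }


_DEFAULTS: Dict[str, Dict] = {
    "cnn": dict(hidden_dim=256, n_layers=3, activation="relu", norm="none",
                readout="max_seq", learning_rate=1e-4),
    "cnn_gru": dict(hidden_dim=64, n_layers=2, activation="relu", norm="none",
                    readout="", learning_rate=1e-4),
    "transformer": dict(hidden_dim=64, n_layers=2, n_heads=4, activation="relu",
                        norm="layer", readout="", learning_rate=1e-4),
    "gcn": dict(hidden_dim=64, n_layers=3, activation="relu", norm="batch",
                readout="weighted_sum_max", learning_rate=1e-5, dtype="float64"),
    "gat": dict(hidden_dim=64, n_layers=3, n_heads=4, activation="relu",
                norm="none", readout="weighted_sum_max", learning_rate=1e-5,
                dtype="float64"),
    "neuralfp": dict(hidden_dim=64, n_layers=3, activation="relu", norm="batch",
                     readout="sum_max", learning_rate=1e-5, dtype="float64"),
    "attentivefp": dict(hidden_dim=64, n_layers=3, activation="relu",
                        norm="none", readout="attentive", learning_rate=1e-5,
                        dtype="float64"),
    "mpnn": dict(hidden_dim=64, n_layers=6, activation="relu", norm="none",
                 readout="sum_max", learning_rate=1e-5, dtype="float64"),
    "pagtn": dict(hidden_dim=64, n_layers=5, activation="leaky_relu",
                  norm="none", readout="weighted_sum_max", learning_rate=1e-5,
                  dtype="float64"),
    "graphormer": dict(hidden_dim=64, n_layers=1, n_heads=8, activation="relu",
                       norm="layer", readout="max", learning_rate=1e-5,
                       dtype="float64"),
    "fixed_embedding": dict(hidden_dim=64, n_layers=1, activation="relu",
                            norm="none", readout="", learning_rate=1e-4,
                            dtype="float64"),
}

_MODEL_CLASSES = {
    "cnn": CNNModel,
    "cnn_gru": CNNGRUModel,
    "transformer": TransformerModel,
    "gcn": GCNModel,
    "gat": GATModel,
    "mpnn": MPNNModel,
    "neuralfp": NeuralFPModel,
    "attentivefp": AttentiveFPModel,
    "pagtn": PAGTNModel,
    "graphormer": GraphormerModel,
}


def default_config(architecture: str, **overrides) -> ModelConfig:
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}; "
                         f"choose from {ARCHITECTURES}")
    kw = dict(_DEFAULTS[architecture])
    kw.update(overrides)
    return ModelConfig(architecture=architecture, **kw)


def default_config_table() -> List[Dict[str, object]]:
    """The full default-configuration table, one dict per architecture."""
    return [default_config(a).table_row()
            for a in SEQUENCE_ARCHITECTURES + GRAPH_ARCHITECTURES]


def build_model(
    architecture: str,
    task_spec: TaskSpec,
    config: Optional[ModelConfig] = None,
    seed: int = 0,
    provider: Optional[EmbeddingProvider] = None,
) -> PredictorModel:
    """Construct a configured architecture for a task.

    Graph architectures and the fixed-embedding head refuse residue-level
    tasks (they produce a single representation per sequence, not one per
    residue).
    """
    if config is None:
        config = default_config(architecture)
    if config.architecture != architecture:
        config = replace(config, architecture=architecture)
    rng = np.random.default_rng(seed)
    if architecture == "fixed_embedding":
        if provider is None:
            provider = kmer_provider()
        return FixedEmbeddingModel(config, task_spec, provider, rng)
    if architecture in GRAPH_ARCHITECTURES and task_spec.level == "residue":
        raise IncompatibleArchitecture(
            f"{architecture} pools atoms to one graph embedding and cannot "
            "emit per-residue predictions")
    if architecture not in _MODEL_CLASSES:
        raise ValueError(f"unknown architecture {architecture!r}")
    return _MODEL_CLASSES[architecture](config, task_spec, rng)


def forward_sequence(model: PredictorModel, batch: ModelBatch):
    """Forward contract wrapper for sequence architectures."""
    if not isinstance(model, SequenceModel):
        raise ShapeMismatch(f"{model.config.architecture} is not a sequence model")
    return model(batch)


def forward_graph(model: PredictorModel, graphs: List[MolecularGraph]):
    """Run a (single-arity) graph architecture directly on molecular graphs."""
    if not isinstance(model, GraphModel):
        raise ShapeMismatch(f"{model.config.architecture} is not a graph model")
    if not graphs:
        raise EmptyGraph("no graphs supplied")
    return model(ModelBatch(inputs=batch_graphs(graphs)))


def save_model(model: PredictorModel, path: str) -> None:
    """Named-parameter archive with the config embedded."""
    state = model.state_dict()
    meta = json.dumps({"config": model.config.to_dict(),
                       "task_spec": asdict(model.task_spec)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_model(path: str, seed: int = 0,
               provider: Optional[EmbeddingProvider] = None) -> PredictorModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_kw = meta["config"]
        arch = cfg_kw.pop("architecture")
        for k in ("conv_filters", "conv_kernels"):
            cfg_kw[k] = tuple(cfg_kw[k])
        config = ModelConfig(architecture=arch, **cfg_kw)
        task_spec = TaskSpec(**meta["task_spec"])
        model = build_model(arch, task_spec, config, seed=seed, provider=provider)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
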
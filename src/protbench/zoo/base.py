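"""Shared forward contract for every architecture in the zoo.

Output shape is a function of the task alone:

* single/pair regression        -> (B,)
* single classification         -> (B, C) logits (softmax + CE downstream)
* pair binary classification    -> (B,) logit  (sigmoid + BCE downstream)
* residue classification        -> (B, L, C) logits
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from ..core import Record, TaskSpec
from ..nn import Dropout, Linear, Module, BatchNorm1d
from ..nn import tensor as T
from ..nn.tensor import Tensor
from .batches import ModelBatch


def activation_fn(name: str):
    if name == "relu":
        return T.relu
    if name == "leaky_relu":
        return lambda x: T.leaky_relu(x, 0.01)
    raise ValueError(f"unknown activation {name!r}")


def output_width(task_spec: TaskSpec) -> int:
    if task_spec.objective == "regression":
        return 1
    if task_spec.arity == "pair" and task_spec.objective == "binary":
        return 1  # single logit, sigmoid + BCE
    return task_spec.num_classes


class MLPHead(Module):
    """One hidden layer + linear output map (the downstream y = WX + b)."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator, activation: str = "relu",
                 norm: str = "none", dropout: float = 0.1, dtype=np.float32):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden, rng, dtype)
        self.fc2 = Linear(hidden, out_dim, rng, dtype)
        self.act = activation_fn(activation)
        self.norm = BatchNorm1d(hidden, dtype=dtype) if norm == "batch" else None
        self.drop = Dropout(dropout)

    def forward(self, x: Tensor) -> Tensor:
        h = self.act(self.fc1(x))
        if self.norm is not None and h.ndim == 2:
            h = self.norm(h)
        return self.fc2(self.drop(h))


class PredictorModel(Module):
    """Base class: a configured architecture with prepare/forward."""

    def __init__(self, config, task_spec: TaskSpec):
        super().__init__()
        self.config = config
        self.task_spec = task_spec

    @property
    def out_dim(self) -> int:
        return output_width(self.task_spec)

    def prepare(self, records: Sequence[Record]) -> ModelBatch:
        raise NotImplementedError

    def forward(self, batch: ModelBatch) -> Tensor:
        raise NotImplementedError

    def squeeze_output(self, out: Tensor) -> Tensor:
        """Drop the trailing singleton for scalar-output tasks."""
        if self.out_dim == 1:
            return T.reshape(out, out.shape[:-1])
        return out
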
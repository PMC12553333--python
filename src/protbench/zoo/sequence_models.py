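"""Sequence-based architectures: CNN, CNN-GRU, and transformer encoder.

All three consume one-hot encoded residue tokens (pad positions are all-zero
and masked at every stage, so padding never influences real positions).
Residue-level tasks reuse the same encoders with a per-position head.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from ..core import PairRecord, ProteinRecord, Record, ResidueRecord, TaskSpec
from ..errors import ShapeMismatch
from ..nn import (
    BiGRU,
    Conv1d,
    Dropout,
    Embedding,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    MultiHeadSelfAttention,
)
from ..nn import tensor as T
from ..nn.tensor import Tensor
from ..sequence_features import (
    DEFAULT_VOCAB,
    EncodedBatch,
    one_hot,
    pad_and_mask,
    tokenize,
)
from .base import MLPHead, PredictorModel, activation_fn
from .batches import ModelBatch

NEG_INF = -1e30


def _encode_sequences(seqs: Sequence[str], max_length: int) -> EncodedBatch:
    return pad_and_mask([tokenize(s, max_length=max_length) for s in seqs])


def _labels_of(records, task_spec: TaskSpec) -> np.ndarray:
    if task_spec.is_classification:
        return np.asarray([r.label for r in records], dtype=np.int64)
    return np.asarray([r.label for r in records], dtype=np.float64)


class SequenceModel(PredictorModel):
    """Common prepare() + pooling/head plumbing for sequence encoders."""

    def prepare(self, records: Sequence[Record]) -> ModelBatch:
        ts = self.task_spec
        max_len = self.config.max_length
        if ts.level == "residue":
            recs: List[ResidueRecord] = list(records)
            enc = _encode_sequences([r.sequence for r in recs], max_len)
            B, L = enc.token_matrix.shape
            labels = np.zeros((B, L), dtype=np.int64)
            for i, r in enumerate(recs):
                labs = r.residue_labels[:max_len]
                labels[i, : len(labs)] = labs
            return ModelBatch(inputs=enc, labels=labels, label_mask=enc.mask,
                              ids=[r.id for r in recs])
        if ts.arity == "pair":
            precs: List[PairRecord] = list(records)
            enc_a = _encode_sequences([r.sequence_a for r in precs], max_len)
            enc_b = _encode_sequences([r.sequence_b for r in precs], max_len)
            return ModelBatch(inputs=(enc_a, enc_b),
                              labels=_labels_of(precs, ts),
                              ids=[r.id for r in precs])
        srecs: List[ProteinRecord] = list(records)
        enc = _encode_sequences([r.sequence for r in srecs], max_len)
        return ModelBatch(inputs=enc, labels=_labels_of(srecs, ts),
                          ids=[r.id for r in srecs])

    # -- implemented by subclasses ---------------------------------------
    def encode(self, enc: EncodedBatch) -> Tensor:
        """Return per-position features (B, L, D)."""
        raise NotImplementedError

    def pool(self, feats: Tensor, enc: EncodedBatch) -> Tensor:
        """Collapse (B, L, D) to (B, D); overridden per architecture."""
        raise NotImplementedError

    def forward(self, batch: ModelBatch) -> Tensor:
        ts = self.task_spec
        if ts.level == "residue":
            feats = self.encode(batch.inputs)
            return self.head(feats)  # (B, L, C)
        if ts.arity == "pair":
            enc_a, enc_b = batch.inputs
            ra = self.pool(self.encode(enc_a), enc_a)
            rb = self.pool(self.encode(enc_b), enc_b)
            rep = T.concat([ra, rb], axis=-1)
            return self.squeeze_output(self.head(rep))
        enc = batch.inputs
        rep = self.pool(self.encode(enc), enc)
        return self.squeeze_output(self.head(rep))


def _masked_max(feats: Tensor, mask: np.ndarray) -> Tensor:
    neg = np.where(mask[:, :, None] > 0, 0.0, NEG_INF).astype(feats.dtype)
    return T.tmax(feats + Tensor(neg), axis=1)


def _masked_mean(feats: Tensor, mask: np.ndarray) -> Tensor:
    m = mask[:, :, None].astype(feats.dtype)
    total = T.tsum(feats * Tensor(m), axis=1)
    return total * Tensor(1.0 / np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
                          .astype(feats.dtype))


class ConvStack(Module):
    """Three same-padding convolution stages with ReLU and mask re-zeroing."""

    def __init__(self, in_dim: int, filters, kernels, rng, activation="relu",
                 dtype=np.float32):
        super().__init__()
        convs = []
        prev = in_dim
        for f, k in zip(filters, kernels):
            convs.append(Conv1d(prev, f, k, rng, padding="same", dtype=dtype))
            prev = f
        self.convs = ModuleList(convs)
        self.act = activation_fn(activation)
        self.out_dim = prev

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        m = Tensor(mask[:, :, None].astype(x.dtype))
        for conv in self.convs:
            x = self.act(conv(x)) * m
        return x


class CNNModel(SequenceModel):
    """1-D CNN: conv stages (32/64/96 filters, kernels 4/8/12), max pooling
    over positions, one-hidden-layer MLP head (hidden 256)."""

    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        dtype = config.np_dtype
        in_dim = len(DEFAULT_VOCAB) - 1
        self.stack = ConvStack(in_dim, config.conv_filters, config.conv_kernels,
                               rng, config.activation, dtype)
        head_in = self.stack.out_dim * (2 if task_spec.arity == "pair" and
                                        task_spec.level == "sequence" else 1)
        self.head = MLPHead(head_in, config.hidden_dim, self.out_dim, rng,
                            config.activation, config.norm, config.dropout, dtype)

    def encode(self, enc: EncodedBatch) -> Tensor:
        x = Tensor(one_hot(enc, dtype=self.config.np_dtype))
        return self.stack(x, enc.mask)

    def pool(self, feats: Tensor, enc: EncodedBatch) -> Tensor:
        return _masked_max(feats, enc.mask)


class CNNGRUModel(SequenceModel):
    """Three convolution stages followed by a 2-layer bidirectional GRU
    (hidden 64), masked-mean pooled."""

    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        dtype = config.np_dtype
        in_dim = len(DEFAULT_VOCAB) - 1
        self.stack = ConvStack(in_dim, config.conv_filters, config.conv_kernels,
                               rng, config.activation, dtype)
        H = config.hidden_dim
        grus = []
        prev = self.stack.out_dim
        for _ in range(config.n_layers):
            grus.append(BiGRU(prev, H, rng, dtype))
            prev = 2 * H
        self.grus = ModuleList(grus)
        self.act = activation_fn(config.activation)
        head_in = prev * (2 if task_spec.arity == "pair" and
                          task_spec.level == "sequence" else 1)
        self.head = MLPHead(head_in, H, self.out_dim, rng, config.activation,
                            config.norm, config.dropout, dtype)

    def encode(self, enc: EncodedBatch) -> Tensor:
        x = Tensor(one_hot(enc, dtype=self.config.np_dtype))
        x = self.stack(x, enc.mask)
        for gru in self.grus:
            x = self.act(gru(x, enc.mask))
        return x

    def pool(self, feats: Tensor, enc: EncodedBatch) -> Tensor:
        return _masked_mean(feats, enc.mask)


class TransformerBlock(Module):
    """Self-attention (+ReLU residual) then MLP with post-LayerNorm."""

    def __init__(self, dim: int, n_heads: int, rng, dropout: float,
                 norm: str, dtype=np.float32):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, dtype)
        self.ff1 = Linear(dim, 4 * dim, rng, dtype)
        self.ff2 = Linear(4 * dim, dim, rng, dtype)
        self.ln = LayerNorm(dim, dtype=dtype) if norm == "layer" else None
        self.drop = Dropout(dropout)

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = x + self.drop(T.relu(self.attn(x, mask)))
        h = self.ff2(self.drop(T.relu(self.ff1(x))))
        x = x + h
        if self.ln is not None:
            x = self.ln(x)
        return x


class TransformerModel(SequenceModel):
    """Transformer encoder: 2 stacked layers, embedding 64, 4 heads,
    learned positional embeddings, masked-mean pooled."""

    def __init__(self, config, task_spec, rng: np.random.Generator):
        super().__init__(config, task_spec)
        dtype = config.np_dtype
        D = config.hidden_dim
        self.embed = Embedding(len(DEFAULT_VOCAB), D, rng, dtype)
        self.pos = Embedding(config.max_length, D, rng, dtype)
        self.blocks = ModuleList([
            TransformerBlock(D, config.n_heads, rng, config.dropout,
                             config.norm, dtype)
            for _ in range(config.n_layers)
        ])
        head_in = D * (2 if task_spec.arity == "pair" and
                       task_spec.level == "sequence" else 1)
        self.head = MLPHead(head_in, D, self.out_dim, rng, config.activation,
                            "none", config.dropout, dtype)

    def encode(self, enc: EncodedBatch) -> Tensor:
        B, L = enc.token_matrix.shape
        x = self.embed(enc.token_matrix) + self.pos(
            np.broadcast_to(np.arange(L), (B, L)))
        x = x * Tensor(enc.mask[:, :, None].astype(x.dtype))
        for blk in self.blocks:
            x = blk(x, enc.mask)
        return x

    def pool(self, feats: Tensor, enc: EncodedBatch) -> Tensor:
        return _masked_mean(feats, enc.mask)
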
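"""Fixed per-sequence embeddings and the trainable head over them.

Mirrors the frozen-encoder workflow: an upstream embedding provider maps a
sequence to a fixed-length vector once (it never receives gradients), and
only a small MLP head trains on top.  Two built-in providers exist: a
k-mer composition embedding (counts of 1..k-mers hashed into the embedding
dimension — a deterministic, information-carrying stand-in labelled
synthetic, not a trained language model) and a hash-seeded random provider
for contract tests.  Externally computed embeddings can be supplied as a
lookup table.
"""

from __future__ import annotations

import hashlib
from itertools import product
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from ..core import CANONICAL_AA, PairRecord, Record, TaskSpec
from ..errors import DimensionMismatch, IncompatibleArchitecture
from ..nn import tensor as T
from ..nn.tensor import Tensor
from .base import MLPHead, PredictorModel
from .batches import ModelBatch

DTYPE = np.float64


class EmbeddingProvider:
    """A frozen sequence -> vector map.  Lookups are cached, so the same
    sequence always yields the identical vector."""

    def __init__(self, name: str, dimension: int,
                 lookup: Callable[[str], np.ndarray]):
        self.name = name
        self.dimension = dimension
        self._lookup = lookup
        self._cache: Dict[str, np.ndarray] = {}

    def lookup(self, sequence: str) -> np.ndarray:
        v = self._cache.get(sequence)
        if v is None:
            v = np.asarray(self._lookup(sequence), dtype=DTYPE)
            if v.shape != (self.dimension,):
                raise DimensionMismatch(
                    f"provider {self.name!r} returned shape {v.shape}, "
                    f"declared dimension {self.dimension}")
            v = v.copy()
            v.setflags(write=False)
            self._cache[sequence] = v
        return v

    def embed_many(self, sequences: Sequence[str]) -> np.ndarray:
        return np.stack([self.lookup(s) for s in sequences])


def hashed_random_provider(dimension: int = 32, salt: str = "protbench") -> EmbeddingProvider:
    """Deterministic pseudo-random unit-scale vectors keyed by sequence hash."""

    def _lookup(seq: str) -> np.ndarray:
        h = hashlib.sha256((salt + seq).encode()).digest()
        rng = np.random.default_rng(int.from_bytes(h[:8], "little"))
        return rng.standard_normal(dimension)

    return EmbeddingProvider(f"hashed_random_{dimension}", dimension, _lookup)


def kmer_provider(dimension: Optional[int] = None, k_max: int = 2,
                  seed: int = 0) -> EmbeddingProvider:
    """k-mer composition embedding: counts of all 1..k_max-mers.

    With ``dimension=None`` every k-mer gets its own exact coordinate
    (420 for k_max=2), so short-motif counts survive unpolluted; passing a
    smaller ``dimension`` hashes k-mers into that many seeded buckets
    (collisions add background noise to every coordinate).
    """
    kmers = ["".join(t) for k in range(1, k_max + 1)
             for t in product(CANONICAL_AA, repeat=k)]
    if dimension is None:
        bucket: Dict[str, int] = {km: i for i, km in enumerate(kmers)}
        dimension = len(kmers)
        name = f"kmer{k_max}_exact"
    else:
        rng = np.random.default_rng(seed)
        bucket = {km: int(rng.integers(0, dimension)) for km in kmers}
        name = f"kmer{k_max}_hash{dimension}"

    def _lookup(seq: str) -> np.ndarray:
        v = np.zeros(dimension)
        for k in range(1, k_max + 1):
            for i in range(len(seq) - k + 1):
                b = bucket.get(seq[i:i + k])
                if b is not None:
                    v[b] += 1.0
        return v

    return EmbeddingProvider(name, dimension, _lookup)


def table_provider(name: str, table: Dict[str, np.ndarray]) -> EmbeddingProvider:
    """Wrap an externally computed per-sequence embedding table."""
    dims = {np.asarray(v).shape for v in table.values()}
    if len(dims) != 1:
        raise DimensionMismatch(f"inconsistent embedding shapes {dims}")
    (dim,) = dims.pop()
    return EmbeddingProvider(name, dim, lambda s: table[s])


class FixedEmbeddingModel(PredictorModel):
    """Trainable MLP head over frozen provider vectors.

    Pair tasks feed the head the concatenation of the two provider vectors
    augmented with the element-wise interaction features |u - v| and u * v
    (the standard frozen-encoder pair representation); interaction-driven
    labels such as shared-motif scores are linear in these features, while
    a plain concatenation forces the small head to rediscover them.
    """

    PAIR_BLOCKS = 4  # u, v, |u - v|, u * v

    def __init__(self, config, task_spec: TaskSpec,
                 provider: EmbeddingProvider, rng: np.random.Generator):
        if task_spec.level == "residue":
            raise IncompatibleArchitecture(
                "fixed per-sequence embeddings carry no per-residue features")
        super().__init__(config, task_spec)
        self.provider = provider
        in_dim = provider.dimension * (self.PAIR_BLOCKS
                                       if task_spec.arity == "pair" else 1)
        self.head = MLPHead(in_dim, config.hidden_dim, self.out_dim, rng,
                            config.activation, config.norm, config.dropout,
                            DTYPE)

    def prepare(self, records: Sequence[Record]) -> ModelBatch:
        ts = self.task_spec
        recs = list(records)
        if ts.arity == "pair":
            u = self.provider.embed_many([r.sequence_a for r in recs])
            v = self.provider.embed_many([r.sequence_b for r in recs])
            x = np.concatenate([u, v, np.abs(u - v), u * v], axis=1)
        else:
            x = self.provider.embed_many([r.sequence for r in recs])
        if ts.is_classification:
            labels = np.asarray([r.label for r in recs], dtype=np.int64)
        else:
            labels = np.asarray([r.label for r in recs], dtype=np.float64)
        return ModelBatch(inputs=x, labels=labels, ids=[r.id for r in recs])

    def forward(self, batch: ModelBatch) -> Tensor:
        return self.squeeze_output(self.head(Tensor(batch.inputs)))
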
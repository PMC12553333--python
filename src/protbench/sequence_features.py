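"""Token encoding of amino-acid sequences for the sequence-based models.

One symbol per residue: pad at index 0, the 20 canonical amino acids
alphabetical at indices 1-20, the unknown symbol at index 21.  Long
sequences are truncated to a maximum length (default 300 residues, kept
from the N-terminus) to bound recurrent-model memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .core import CANONICAL_AA, UNKNOWN_AA
from .errors import EmptyBatch, EmptySequence

MAX_LENGTH = 300


@dataclass(frozen=True)
class TokenVocabulary:
    symbols: tuple = ("<pad>",) + tuple(CANONICAL_AA) + (UNKNOWN_AA,)
    pad_index: int = 0

    @property
    def unknown_index(self) -> int:
        return len(self.symbols) - 1

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, ch: str) -> int:
        i = CANONICAL_AA.find(ch)
        return i + 1 if i >= 0 else self.unknown_index


DEFAULT_VOCAB = TokenVocabulary()


@dataclass
class EncodedBatch:
    """Right-padded integer token matrix with a parallel 0/1 mask."""

    token_matrix: np.ndarray          # (B, L) int
    mask: np.ndarray                  # (B, L) float, 1 = real residue
    labels: Optional[np.ndarray] = None

    @property
    def lengths(self) -> np.ndarray:
        return self.mask.sum(axis=1).astype(int)


def tokenize(
    sequence: str,
    vocab: TokenVocabulary = DEFAULT_VOCAB,
    max_length: int = MAX_LENGTH,
) -> List[int]:
    """Map a sequence to token indices, truncating to ``max_length`` residues.

    Unknown characters map to the unknown index; the result never contains
    the pad token.
    """
    if not sequence:
        raise EmptySequence("cannot tokenize an empty sequence")
    return [vocab.index(ch) for ch in sequence.upper()[:max_length]]


def detokenize(tokens: Sequence[int], vocab: TokenVocabulary = DEFAULT_VOCAB) -> str:
    return "".join(vocab.symbols[t] for t in tokens if t != vocab.pad_index)


def pad_and_mask(
    token_lists: Sequence[Sequence[int]],
    labels: Optional[np.ndarray] = None,
    vocab: TokenVocabulary = DEFAULT_VOCAB,
) -> EncodedBatch:
    """Right-pad token lists to the batch maximum and record the mask."""
    if len(token_lists) == 0:
        raise EmptyBatch("no token lists to batch")
    if any(len(t) == 0 for t in token_lists):
        raise EmptySequence("token lists must be non-empty")
    max_len = max(len(t) for t in token_lists)
    mat = np.full((len(token_lists), max_len), vocab.pad_index, dtype=np.int64)
    mask = np.zeros((len(token_lists), max_len), dtype=np.float32)
    for i, toks in enumerate(token_lists):
        mat[i, : len(toks)] = toks
        mask[i, : len(toks)] = 1.0
    return EncodedBatch(token_matrix=mat, mask=mask,
                        labels=None if labels is None else np.asarray(labels))


def one_hot(batch: EncodedBatch, vocab: TokenVocabulary = DEFAULT_VOCAB,
            dtype=np.float32) -> np.ndarray:
    """One-hot encode a batch, (B, L, |vocab|-1): pad rows are all-zero.

    The pad symbol has no coordinate, so each real position's row sums to 1
    and the row sums reproduce the mask exactly.
    """
    n_sym = len(vocab) - 1  # pad excluded
    out = np.zeros(batch.token_matrix.shape + (n_sym,), dtype=dtype)
    real = batch.token_matrix != vocab.pad_index
    b, l = np.nonzero(real)
    out[b, l, batch.token_matrix[b, l] - 1] = 1.0
    return out
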
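"""Seeded planted-motif generators for all five task types.

Each generator plants short amino-acid motifs into otherwise uniform random
sequences and derives the label from the planted signal, so ground truth is
known by construction and a simple motif scan upper-bounds what any trained
model can reach.  Label noise (Gaussian for regression, flips for
classification) is applied after balancing; records keep the pre-noise
truth in ``clean_label`` / ``clean_labels`` so learnability can be scored
against the planted signal while training sees the noisy observations.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    CANONICAL_AA,
    PairRecord,
    ProteinRecord,
    ResidueRecord,
    TaskSpec,
)
from .errors import InvalidSpec

DEFAULT_LENGTH_RANGE = (50, 200)


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic dataset.

    ``noise`` is the Gaussian label s.d. for regression tasks and the label
    flip probability (in [0, 0.5)) for classification tasks.
    ``max_insertions`` bounds how many copies of each motif one sequence
    receives (drawn uniformly from 0..max for count-driven labels).
    """

    task_spec: TaskSpec
    n_samples: int = 2000
    length_range: Tuple[int, int] = DEFAULT_LENGTH_RANGE
    motifs: Tuple[str, ...] = ("WKW",)
    motif_weights: Optional[Tuple[float, ...]] = None
    noise: float = 0.0
    seed: int = 0
    max_insertions: int = 3
    motifs_per_seq: int = 2  # residue-level generator only

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_samples <= 0:
            raise InvalidSpec("n_samples must be positive")
        if lo > hi or lo <= 0:
            raise InvalidSpec(f"bad length range {self.length_range}")
        if not self.motifs:
            raise InvalidSpec("at least one motif is required")
        for m in self.motifs:
            if not m or any(ch not in CANONICAL_AA for ch in m):
                raise InvalidSpec(f"motif {m!r} must be canonical amino acids")
            if len(m) > lo:
                raise InvalidSpec(f"motif {m!r} longer than min length {lo}")
        if self.noise < 0:
            raise InvalidSpec("noise must be >= 0")
        if self.task_spec.is_classification and not self.noise < 0.5:
            raise InvalidSpec("flip probability must be < 0.5")

    @property
    def weights(self) -> Tuple[float, ...]:
        if self.motif_weights is None:
            return tuple(1.0 for _ in self.motifs)
        return self.motif_weights


def _random_sequence(rng: np.random.Generator, length: int,
                     forbidden: Sequence[str] = ()) -> str:
    """Uniform sequence over the canonical alphabet, rejection-sampled so
    that none of ``forbidden`` occurs by chance."""
    letters = np.array(list(CANONICAL_AA))
    for _ in range(200):
        seq = "".join(rng.choice(letters, size=length))
        if not any(m in seq for m in forbidden):
            return seq
    raise InvalidSpec("could not sample a sequence avoiding the motifs")


def _insert_motif(rng: np.random.Generator, seq: str, motif: str) -> Tuple[str, int]:
    """Overwrite a random window with the motif; returns (sequence, start)."""
    start = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:start] + motif + seq[start + len(motif):], start


def count_occurrences(seq: str, motif: str) -> int:
    """Overlapping occurrence count (the label-defining scan)."""
    count, start = 0, 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def gen_single_regression(spec: GeneratorSpec) -> List[ProteinRecord]:
    """label = sum_m weight_m * count(motif_m) + N(0, noise)."""
    rng = np.random.default_rng(spec.seed)
    records = []
    lo, hi = spec.length_range
    for i in range(spec.n_samples):
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        for m in spec.motifs:
            for _ in range(int(rng.integers(0, spec.max_insertions + 1))):
                seq, _ = _insert_motif(rng, seq, m)
        clean = float(sum(w * count_occurrences(seq, m)
                          for m, w in zip(spec.motifs, spec.weights)))
        label = clean + (rng.normal(0.0, spec.noise) if spec.noise else 0.0)
        records.append(ProteinRecord(id=f"reg{i:05d}", sequence=seq,
                                     label=label, clean_label=clean))
    return records


def gen_single_classification(spec: GeneratorSpec) -> List[ProteinRecord]:
    """Class c sequences contain motif_c (and none of the other class
    motifs); classes balanced to +-1; labels flipped with prob ``noise``."""
    C = spec.task_spec.num_classes
    if len(spec.motifs) != C:
        raise InvalidSpec(f"need {C} class motifs, got {len(spec.motifs)}")
    rng = np.random.default_rng(spec.seed)
    records = []
    lo, hi = spec.length_range
    for i in range(spec.n_samples):
        c = i % C  # balanced to +-1 by construction
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)),
                               forbidden=spec.motifs)
        for _ in range(1 + int(rng.integers(0, spec.max_insertions))):
            seq, _ = _insert_motif(rng, seq, spec.motifs[c])
        label = c
        if spec.noise and rng.random() < spec.noise:
            label = int((c + 1 + rng.integers(0, C - 1)) % C) if C > 2 else 1 - c
        records.append(ProteinRecord(id=f"cls{i:05d}", sequence=seq,
                                     label=label, clean_label=c))
    order = rng.permutation(len(records))
    return [records[j] for j in order]


def gen_pair(spec: GeneratorSpec) -> List[PairRecord]:
    """Protein-pair tasks.

    Regression: label = sum_m weight_m * min(count_a, count_m_b) + noise —
    a symmetric shared-motif score (swapping the two sequences leaves the
    label unchanged).  Classification: positives carry a complementary
    motif pair (motif_0 in one sequence, motif_1 in the other); labels
    flipped with prob ``noise``.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    lo, hi = spec.length_range
    if spec.task_spec.is_classification:
        if len(spec.motifs) < 2:
            raise InvalidSpec("pair classification needs >= 2 motifs")
        m0, m1 = spec.motifs[0], spec.motifs[1]
        for i in range(spec.n_samples):
            pos = i % 2 == 1
            a = _random_sequence(rng, int(rng.integers(lo, hi + 1)),
                                 forbidden=spec.motifs)
            b = _random_sequence(rng, int(rng.integers(lo, hi + 1)),
                                 forbidden=spec.motifs)
            if pos:  # complementary pair, random orientation
                first, second = (m0, m1) if rng.random() < 0.5 else (m1, m0)
                a, _ = _insert_motif(rng, a, first)
                b, _ = _insert_motif(rng, b, second)
            else:  # same motif on both sides: not complementary
                m = m0 if rng.random() < 0.5 else m1
                a, _ = _insert_motif(rng, a, m)
                b, _ = _insert_motif(rng, b, m)
            clean = int(pos)
            label = clean
            if spec.noise and rng.random() < spec.noise:
                label = 1 - label
            records.append(PairRecord(id=f"pair{i:05d}", sequence_a=a,
                                      sequence_b=b, label=label,
                                      clean_label=clean))
    else:
        for i in range(spec.n_samples):
            a = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            b = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            for m in spec.motifs:
                for _ in range(int(rng.integers(0, spec.max_insertions + 1))):
                    a, _ = _insert_motif(rng, a, m)
                for _ in range(int(rng.integers(0, spec.max_insertions + 1))):
                    b, _ = _insert_motif(rng, b, m)
            clean = float(sum(
                w * min(count_occurrences(a, m), count_occurrences(b, m))
                for m, w in zip(spec.motifs, spec.weights)))
            label = clean + (rng.normal(0.0, spec.noise) if spec.noise else 0.0)
            records.append(PairRecord(id=f"pair{i:05d}", sequence_a=a,
                                      sequence_b=b, label=label,
                                      clean_label=clean))
    order = rng.permutation(len(records))
    return [records[j] for j in order]


def gen_residue(spec: GeneratorSpec) -> List[ResidueRecord]:
    """Residue label 1 exactly at inserted-motif positions, 0 elsewhere,
    then positionwise flips with prob ``noise``."""
    rng = np.random.default_rng(spec.seed)
    records = []
    lo, hi = spec.length_range
    for i in range(spec.n_samples):
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)),
                               forbidden=spec.motifs)
        labels = np.zeros(len(seq), dtype=int)
        for _ in range(spec.motifs_per_seq):
            m = spec.motifs[int(rng.integers(0, len(spec.motifs)))]
            # keep planted motifs disjoint so position labels stay exact
            for _try in range(50):
                start = int(rng.integers(0, len(seq) - len(m) + 1))
                if not labels[start:start + len(m)].any():
                    break
            seq = seq[:start] + m + seq[start + len(m):]
            labels[start:start + len(m)] = 1
        clean = labels.copy()
        if spec.noise:
            flips = rng.random(len(seq)) < spec.noise
            labels = np.where(flips, 1 - labels, labels)
        records.append(ResidueRecord(id=f"res{i:05d}", sequence=seq,
                                     residue_labels=labels.tolist(),
                                     clean_labels=clean.tolist()))
    return records


def generate(spec: GeneratorSpec):
    """Dispatch on the task declaration."""
    ts = spec.task_spec
    if ts.level == "residue":
        return gen_residue(spec)
    if ts.arity == "pair":
        return gen_pair(spec)
    if ts.objective == "regression":
        return gen_single_regression(spec)
    return gen_single_classification(spec)
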
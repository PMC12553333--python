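"""Domain data model: task declarations, labeled records, splits, train config.

A task is declared once as a :class:`TaskSpec` (arity, level, objective) and
every downstream stage — featurization, head construction, loss selection,
metric selection — is conditioned on it.  Records come in three shapes:
one protein with one label, a protein pair with one label, or one protein
with one class label per residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    EmptySequence,
    LabelOutOfRange,
    LengthMismatch,
    TooFewRecords,
)

#: The 20 canonical amino acids, alphabetical one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Symbol every non-canonical / ambiguous residue (B, Z, U, O, ...) maps to.
UNKNOWN_AA = "X"

Label = Union[float, int]


@dataclass(frozen=True)
class TaskSpec:
    """Declares one of the five machine-learning task types.

    arity
        ``"single"`` (one protein to one aim) or ``"pair"`` (two proteins
        to one aim, e.g. PPI or antibody heavy/light chains).
    level
        ``"sequence"`` for one label per record, ``"residue"`` for one
        class label per amino-acid position (epitope/paratope-style).
    objective
        ``"regression"``, ``"binary"`` or ``"multiclass"``.
    """

    name: str
    arity: str = "single"
    level: str = "sequence"
    objective: str = "regression"
    num_classes: int = 2

    def __post_init__(self) -> None:
        if self.arity not in ("single", "pair"):
            raise ValueError(f"arity must be single|pair, got {self.arity!r}")
        if self.level not in ("sequence", "residue"):
            raise ValueError(f"level must be sequence|residue, got {self.level!r}")
        if self.objective not in ("regression", "binary", "multiclass"):
            raise ValueError(f"bad objective {self.objective!r}")
        if self.level == "residue" and self.arity != "single":
            raise ValueError("residue-level tasks are single-arity only")
        if self.objective == "binary" and self.num_classes != 2:
            raise ValueError("binary tasks have num_classes = 2")
        if self.objective == "multiclass" and self.num_classes < 3:
            raise ValueError("multiclass tasks need num_classes >= 3")

    @property
    def is_classification(self) -> bool:
        return self.objective != "regression"


@dataclass
class ProteinRecord:
    """One protein sequence with a scalar label (real value or class index)."""

    id: str
    sequence: str
    label: Label = 0.0
    #: Planted (pre label-noise) truth, populated by the synthetic generators.
    clean_label: Optional[Label] = None


@dataclass
class PairRecord:
    """Two protein sequences with one joint label (PPI / antibody chains)."""

    id: str
    sequence_a: str
    sequence_b: str
    label: Label = 0.0
    clean_label: Optional[Label] = None


@dataclass
class ResidueRecord:
    """One protein with a class label for every residue position."""

    id: str
    sequence: str
    residue_labels: List[int] = field(default_factory=list)
    clean_labels: Optional[List[int]] = None


Record = Union[ProteinRecord, PairRecord, ResidueRecord]


@dataclass
class DatasetSplit:
    train: List[Record]
    valid: List[Record]
    test: List[Record]
    seed: int = 0

    def __iter__(self):
        yield from (self.train, self.valid, self.test)

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.valid) + len(self.test)


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the shipped baseline configs
    (batch 32, up to 100 epochs, dropout 0.1, Adam).

    ``early_stop_patience`` (optional) stops training once the validation
    headline metric has not improved for that many epochs and restores the
    best-epoch weights; ``None`` trains to ``max_epochs`` and returns the
    final-epoch model.
    """

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    seed: int = 0
    dropout: float = 0.1
    early_stop_patience: Optional[int] = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _clean_sequence(seq: str, rec_id: str) -> str:
    if not seq:
        raise EmptySequence(f"record {rec_id!r} has an empty sequence")
    seq = seq.upper()
    cleaned = []
    n_unknown = 0
    for ch in seq:
        if ch in CANONICAL_AA or ch == UNKNOWN_AA:
            cleaned.append(ch)
        else:
            cleaned.append(UNKNOWN_AA)
            n_unknown += 1
    if n_unknown:
        warnings.warn(
            f"record {rec_id!r}: {n_unknown} non-canonical residue(s) mapped "
            f"to the unknown symbol {UNKNOWN_AA!r}",
            stacklevel=3,
        )
    return "".join(cleaned)


def validate_records(records: Sequence[Record], task_spec: TaskSpec) -> List[Record]:
    """Validate and normalize records against a task declaration.

    Unknown residues are mapped to the unknown token (with a warning);
    empty sequences, residue-label length mismatches and out-of-range class
    labels raise.  Validation is idempotent.
    """
    out: List[Record] = []
    for rec in records:
        if task_spec.level == "residue":
            if not isinstance(rec, ResidueRecord):
                raise TypeError(f"expected ResidueRecord, got {type(rec).__name__}")
            seq = _clean_sequence(rec.sequence, rec.id)
            if len(rec.residue_labels) != len(seq):
                raise LengthMismatch(
                    f"record {rec.id!r}: {len(rec.residue_labels)} labels for "
                    f"{len(seq)} residues"
                )
            for lab in rec.residue_labels:
                if not 0 <= int(lab) < task_spec.num_classes:
                    raise LabelOutOfRange(
                        f"record {rec.id!r}: residue label {lab} outside "
                        f"[0, {task_spec.num_classes})"
                    )
            out.append(replace(rec, sequence=seq,
                               residue_labels=[int(l) for l in rec.residue_labels]))
        elif task_spec.arity == "pair":
            if not isinstance(rec, PairRecord):
                raise TypeError(f"expected PairRecord, got {type(rec).__name__}")
            a = _clean_sequence(rec.sequence_a, rec.id)
            b = _clean_sequence(rec.sequence_b, rec.id)
            out.append(replace(rec, sequence_a=a, sequence_b=b,
                               label=_check_label(rec.label, task_spec, rec.id)))
        else:
            if not isinstance(rec, ProteinRecord):
                raise TypeError(f"expected ProteinRecord, got {type(rec).__name__}")
            seq = _clean_sequence(rec.sequence, rec.id)
            out.append(replace(rec, sequence=seq,
                               label=_check_label(rec.label, task_spec, rec.id)))
    return out


def _check_label(label: Label, task_spec: TaskSpec, rec_id: str) -> Label:
    if task_spec.is_classification:
        lab = int(label)
        if not 0 <= lab < task_spec.num_classes:
            raise LabelOutOfRange(
                f"record {rec_id!r}: class label {lab} outside "
                f"[0, {task_spec.num_classes})"
            )
        return lab
    return float(label)


def make_split(
    records: Sequence[Record],
    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded random train/valid/test partition with rounded ratio shares.

    Every record lands in exactly one part; identical (records, ratios, seed)
    always yields the identical partition.
    """
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive numbers")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(records)
    n_train = int(round(ratios[0] * n))
    n_valid = int(round(ratios[1] * n))
    n_test = n - n_train - n_valid
    if min(n_train, n_valid, n_test) <= 0:
        raise TooFewRecords(
            f"{n} records cannot fill a {ratios} split without an empty part"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    recs = [records[i] for i in order]
    return DatasetSplit(
        train=recs[:n_train],
        valid=recs[n_train:n_train + n_valid],
        test=recs[n_train + n_valid:],
        seed=seed,
    )
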
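"""File formats: FASTA input, CSV task tables, JSON reports.

Task tables are CSV with header ``id,sequence[,sequence_b],label``; residue
labels are encoded as a digit string of the same length as the sequence.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .core import (
    PairRecord,
    ProteinRecord,
    Record,
    ResidueRecord,
    TaskSpec,
    validate_records,
)
from .errors import LengthMismatch, MalformedFasta, MissingColumn

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> List[ProteinRecord]:
    """Unlabeled records from FASTA; header up to the first whitespace is
    the id, wrapped sequence lines are concatenated and uppercased."""
    text = Path(path).read_text()
    if not text.lstrip().startswith(">"):
        raise MalformedFasta(f"{path}: no FASTA header found")
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise MalformedFasta(f"{path}: no sequences parsed")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_task_table(path: PathLike, task_spec: TaskSpec) -> List[Record]:
    """Validated records from a CSV task table for the given task shape."""
    df = pd.read_csv(path, dtype={"id": str, "sequence": str,
                                  "sequence_b": str, "label": str})
    required = {"id", "sequence", "label"}
    if task_spec.arity == "pair":
        required.add("sequence_b")
    missing = required - set(df.columns)
    if missing:
        raise MissingColumn(f"{path}: missing column(s) {sorted(missing)}")
    records: List[Record] = []
    for row in df.itertuples(index=False):
        if task_spec.level == "residue":
            labels = str(row.label)
            if len(labels) != len(row.sequence):
                raise LengthMismatch(
                    f"{path}: record {row.id!r} has {len(labels)} residue "
                    f"labels for {len(row.sequence)} residues")
            records.append(ResidueRecord(
                id=row.id, sequence=row.sequence,
                residue_labels=[int(c) for c in labels]))
        elif task_spec.arity == "pair":
            records.append(PairRecord(
                id=row.id, sequence_a=row.sequence, sequence_b=row.sequence_b,
                label=_parse_label(row.label, task_spec)))
        else:
            records.append(ProteinRecord(
                id=row.id, sequence=row.sequence,
                label=_parse_label(row.label, task_spec)))
    return validate_records(records, task_spec)


def _parse_label(raw: str, task_spec: TaskSpec):
    return int(raw) if task_spec.is_classification else float(raw)


def write_task_table(records: Sequence[Record], path: PathLike,
                     task_spec: TaskSpec) -> None:
    rows = []
    for rec in records:
        if task_spec.level == "residue":
            rows.append({"id": rec.id, "sequence": rec.sequence,
                         "label": "".join(str(l) for l in rec.residue_labels)})
        elif task_spec.arity == "pair":
            rows.append({"id": rec.id, "sequence": rec.sequence_a,
                         "sequence_b": rec.sequence_b, "label": rec.label})
        else:
            rows.append({"id": rec.id, "sequence": rec.sequence,
                         "label": rec.label})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    try:
        return o.item()  # numpy scalars
    except AttributeError:
        return str(o)
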
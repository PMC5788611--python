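"""Reading, validating and labelling DNA sequence sets.

A classification dataset is the union of a positive set (DNase I
hypersensitive sites, DHSs) and a negative set (non-DHSs), kept in file
order with parallel binary labels. Sequences are plain A/C/G/T strings;
soft-masked (lowercase) input is uppercased on ingest and ambiguity codes
are rejected by default because every downstream encoding is defined only
on the four standard bases.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "LabeledDataset",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "load_labeled_dataset",
    "dataset_manifest",
]

VALID_BASES = frozenset("ACGT")

#: integer codes used by the label vector
LABEL_POSITIVE = 1
LABEL_NEGATIVE = 0


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid sequence content."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A validated DNA sequence with a non-empty identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("record identifier must be non-empty")
        if not self.seq:
            raise FastaError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def _validate_bases(rec_id: str, seq: str) -> str:
    seq = seq.upper()
    for pos, base in enumerate(seq, start=1):
        if base not in VALID_BASES:
            raise FastaError(
                f"record {rec_id!r}: disallowed character {base!r} at position {pos}"
            )
    return seq


def read_fasta(
    path: str | Path,
    ambiguous: Literal["strict", "drop"] = "strict",
) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file (multi-record; wrapped or unwrapped lines).
    ambiguous
        ``"strict"`` (default) raises :class:`FastaError` on any non-ACGT
        character, naming the record and 1-based position; ``"drop"``
        silently discards records containing such characters.

    Order is preserved and sequences are uppercased. An empty file yields
    an empty list. Duplicate identifiers within the file are an error.
    """
    if ambiguous not in ("strict", "drop"):
        raise ValueError(f"unknown ambiguity policy: {ambiguous!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        head = handle.read(1)
        while head and head.isspace():
            head = handle.read(1)
        if head and head != ">":
            raise FastaError("malformed FASTA: content before first '>' header")
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else ""
            if not rec_id:
                raise FastaError(f"malformed header {header!r}: empty identifier")
            if rec_id in seen:
                raise FastaError(f"duplicate record id {rec_id!r}")
            seq = seq.replace(" ", "")
            if not seq:
                raise FastaError(f"record {rec_id!r}: empty sequence")
            try:
                seq = _validate_bases(rec_id, seq)
            except FastaError:
                if ambiguous == "drop":
                    continue
                raise
            seen.add(rec_id)
            records.append(SequenceRecord(rec_id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")


@dataclasses.dataclass
class LabeledDataset:
    """Ordered sequence records with parallel binary labels.

    ``labels`` is an int8 vector with 1 for the positive (DHS) class and
    0 for the negative class; positives precede negatives when built by
    :func:`load_labeled_dataset`.
    """

    records: list[SequenceRecord]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels must be parallel")
        if not set(np.unique(self.labels)) <= {LABEL_NEGATIVE, LABEL_POSITIVE}:
            raise ValueError("labels must be binary (0/1)")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FastaError(f"duplicate record id {dup!r} within dataset")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_pos(self) -> int:
        return int((self.labels == LABEL_POSITIVE).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == LABEL_NEGATIVE).sum())

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices], self.labels[list(indices)]
        )


def load_labeled_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    ambiguous: Literal["strict", "drop"] = "strict",
) -> LabeledDataset:
    """Build a labelled dataset from a positive and a negative FASTA file.

    Records keep their file order (all positives first); identifiers must
    be unique across the union and both classes must be non-empty.
    """
    pos = read_fasta(pos_path, ambiguous=ambiguous)
    neg = read_fasta(neg_path, ambiguous=ambiguous)
    if not pos:
        raise FastaError(f"positive set {pos_path} is empty")
    if not neg:
        raise FastaError(f"negative set {neg_path} is empty")
    labels = np.concatenate(
        [np.ones(len(pos), dtype=np.int8), np.zeros(len(neg), dtype=np.int8)]
    )
    return LabeledDataset(pos + neg, labels)


def dataset_manifest(dataset: LabeledDataset) -> pd.DataFrame:
    """Tabular summary of a dataset: id, label, length (one row per record)."""
    return pd.DataFrame(
        {
            "id": dataset.ids,
            "label": ["positive" if l else "negative" for l in dataset.labels],
            "length": [len(r) for r in dataset.records],
        }
    )
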
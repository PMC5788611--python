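"""Sequence feature encoders: k-mer compositions and physicochemical profiles.

Three feature families are produced, all from overlapping windows:

* ``k``-mer composition — the fraction of each of the 4^k length-``k``
  substrings among the L−k+1 windows of a length-L sequence. Blocks MNC,
  DNC, TNC, TeNC, PNC correspond to k = 1..5 (4, 16, 64, 256 and 1024
  features).
* DPCP — dinucleotide physicochemical properties: for each of the 6
  normalized base-pair-step properties and each of the 16 dinucleotides,
  count(dinucleotide) x property / L. 96 features.
* TPCP — trinucleotide physicochemical properties: same construction over
  64 trinucleotides and 12 properties. 768 features.

The full seven-block encoding is 2228 features in the canonical order
MNC, DNC, TNC, TeNC, PNC, DPCP, TPCP. Feature names are block-prefixed
(``kmer2:AC``, ``dpcp:twist:AC``, ``tpcp:gc_content:ACG``) and their order
is part of the public contract: saved models remain valid only against it.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .properties import (
    PropertyTable,
    default_dinucleotide_table,
    default_trinucleotide_table,
)
from .seqio import LabeledDataset, SequenceRecord

__all__ = [
    "BLOCK_ORDER",
    "BLOCK_SIZES",
    "EncodingLengthError",
    "kmer_composition",
    "dpcp",
    "tpcp",
    "encode",
    "block_feature_names",
]

#: canonical block order for concatenated encodings
BLOCK_ORDER = ("MNC", "DNC", "TNC", "TeNC", "PNC", "DPCP", "TPCP")

KMER_BLOCKS = {"MNC": 1, "DNC": 2, "TNC": 3, "TeNC": 4, "PNC": 5}

#: feature-vector width of each block
BLOCK_SIZES = {
    "MNC": 4,
    "DNC": 16,
    "TNC": 64,
    "TeNC": 256,
    "PNC": 1024,
    "DPCP": 96,
    "TPCP": 768,
}

#: minimum sequence length each block requires
BLOCK_MIN_LENGTH = {"MNC": 1, "DNC": 2, "TNC": 3, "TeNC": 4, "PNC": 5, "DPCP": 2, "TPCP": 3}

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class EncodingLengthError(ValueError):
    """A sequence is shorter than an encoder's minimum length."""


def _codes(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = int(np.argmax(arr < 0))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad + 1}")
    return arr


def _window_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of the 4^k overlapping k-mers, lexicographic order."""
    n_win = codes.size - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    for offset in range(k):
        idx = idx * 4 + codes[offset : offset + n_win]
    return np.bincount(idx, minlength=4**k)


def _as_record(seq: SequenceRecord | str) -> SequenceRecord:
    if isinstance(seq, SequenceRecord):
        return seq
    return SequenceRecord("seq", str(seq).upper())


def _kmer_names(k: int) -> list[str]:
    return [f"kmer{k}:{''.join(p)}" for p in itertools.product("ACGT", repeat=k)]


def kmer_composition(seq: SequenceRecord | str, k: int) -> pd.Series:
    """Fractional composition of overlapping k-mers (k = 1..5).

    Returns a length-4^k Series over lexicographically ordered k-mers;
    values are counts / (L−k+1) and sum to 1.
    """
    if not 1 <= k <= 5:
        raise ValueError("k must be in 1..5")
    rec = _as_record(seq)
    if len(rec) < k:
        raise EncodingLengthError(
            f"record {rec.id!r}: length {len(rec)} < k={k}"
        )
    counts = _window_counts(_codes(rec.seq), k)
    return pd.Series(counts / counts.sum(), index=_kmer_names(k), dtype=float)


NresConvention = Literal["length", "windows"]


def _pcp(
    rec: SequenceRecord,
    table: PropertyTable,
    prefix: str,
    nres: NresConvention,
) -> pd.Series:
    n = table.order
    if len(rec) < n:
        raise EncodingLengthError(
            f"record {rec.id!r}: length {len(rec)} < {n} required by {prefix.upper()}"
        )
    if not table.normalized:
        raise ValueError("property table must be normalized before encoding")
    counts = _window_counts(_codes(rec.seq), n).astype(float)
    denom = float(len(rec)) if nres == "length" else float(len(rec) - n + 1)
    # property-major layout: all n-mers of property 1, then property 2, ...
    vals = np.concatenate(
        [counts * table.values[prop].to_numpy() / denom for prop in table.properties]
    )
    nmers = list(table.values.index)
    names = [f"{prefix}:{prop}:{m}" for prop in table.properties for m in nmers]
    return pd.Series(vals, index=names, dtype=float)


def dpcp(
    seq: SequenceRecord | str,
    table: PropertyTable | None = None,
    nres: NresConvention = "length",
) -> pd.Series:
    """Dinucleotide physicochemical profile: 16 x 6 = 96 features.

    Feature (property i, dinucleotide j) = count(j) x table[i, j] / N_res,
    with N_res the sequence length L by default (``nres="windows"`` uses
    L−1 instead, which only rescales the block).
    """
    return _pcp(_as_record(seq), table or default_dinucleotide_table(), "dpcp", nres)


def tpcp(
    seq: SequenceRecord | str,
    table: PropertyTable | None = None,
    nres: NresConvention = "length",
) -> pd.Series:
    """Trinucleotide physicochemical profile: 64 x 12 = 768 features."""
    return _pcp(_as_record(seq), table or default_trinucleotide_table(), "tpcp", nres)


def block_feature_names(
    blocks: Sequence[str],
    di_table: PropertyTable | None = None,
    tri_table: PropertyTable | None = None,
) -> list[str]:
    """Feature names for the given blocks in canonical order."""
    di = di_table or default_dinucleotide_table()
    tri = tri_table or default_trinucleotide_table()
    names: list[str] = []
    for block in _canonical(blocks):
        if block in KMER_BLOCKS:
            names.extend(_kmer_names(KMER_BLOCKS[block]))
        elif block == "DPCP":
            names.extend(
                f"dpcp:{p}:{m}" for p in di.properties for m in di.values.index
            )
        else:
            names.extend(
                f"tpcp:{p}:{m}" for p in tri.properties for m in tri.values.index
            )
    return names


def _canonical(blocks: Iterable[str]) -> list[str]:
    blocks = list(blocks)
    if not blocks:
        raise ValueError("empty block list")
    unknown = [b for b in blocks if b not in BLOCK_ORDER]
    if unknown:
        raise ValueError(f"unknown block(s) {unknown}; valid: {list(BLOCK_ORDER)}")
    return [b for b in BLOCK_ORDER if b in set(blocks)]


def encode(
    dataset: LabeledDataset,
    blocks: Sequence[str] = BLOCK_ORDER,
    di_table: PropertyTable | None = None,
    tri_table: PropertyTable | None = None,
    nres: NresConvention = "length",
) -> pd.DataFrame:
    """Encode every sequence of a dataset into a feature matrix.

    Columns are the requested blocks concatenated in canonical order
    (all seven blocks -> 2228 columns); rows follow dataset order and are
    indexed by record id. ``.attrs["block_of"]`` maps each column to its
    block and ``.attrs["blocks"]`` records the block list used.

    Raises :class:`EncodingLengthError` listing every record shorter than
    the most demanding requested block.
    """
    blocks = _canonical(blocks)
    min_len = max(BLOCK_MIN_LENGTH[b] for b in blocks)
    too_short = [r.id for r in dataset.records if len(r) < min_len]
    if too_short:
        raise EncodingLengthError(
            f"{len(too_short)} record(s) shorter than {min_len} nt required "
            f"by blocks {blocks}: {too_short[:10]}"
        )
    di = di_table or default_dinucleotide_table()
    tri = tri_table or default_trinucleotide_table()

    parts: list[np.ndarray] = []
    for rec in dataset.records:
        row: list[np.ndarray] = []
        codes = _codes(rec.seq)
        for block in blocks:
            if block in KMER_BLOCKS:
                k = KMER_BLOCKS[block]
                counts = _window_counts(codes, k)
                row.append(counts / counts.sum())
            elif block == "DPCP":
                row.append(_pcp(rec, di, "dpcp", nres).to_numpy())
            else:
                row.append(_pcp(rec, tri, "tpcp", nres).to_numpy())
        parts.append(np.concatenate(row))

    names = block_feature_names(blocks, di, tri)
    X = pd.DataFrame(np.vstack(parts), index=dataset.ids, columns=names)
    block_of: dict[str, str] = {}
    for block in blocks:
        for name in block_feature_names([block], di, tri):
            block_of[name] = block
    X.attrs["blocks"] = list(blocks)
    X.attrs["block_of"] = block_of
    return X
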
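"""Physicochemical property tables for di- and trinucleotides.

A :class:`PropertyTable` holds one real value per n-mer (lexicographic
order, A<C<G<T) and property. Tables are min-max normalized per property
column to [0, 1] before use, so the downstream physicochemical features
are scale-free; raw tables with any units can be supplied.

The bundled default tables are synthetic stand-ins with realistic
structure (see ``data/*_synthetic.tsv``): the dinucleotide table carries
representative crystallographic base-pair-step averages for shift, slide,
rise, twist, tilt and roll (reverse-complement symmetry respected); the
trinucleotide table carries twelve properties of which GC content and the
two molecular-weight columns are computed exactly and the nine
experimental scales (bendability, nucleosome positioning/affinity,
DNase I sensitivity, consensus roll/rigidity) are seeded synthetic values.
Studies of real data should supply measured tables in the same schema.
"""

from __future__ import annotations

import dataclasses
import itertools
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PropertyTable",
    "normalize_property_table",
    "load_property_table",
    "default_dinucleotide_table",
    "default_trinucleotide_table",
    "N_DINUCLEOTIDE_PROPERTIES",
    "N_TRINUCLEOTIDE_PROPERTIES",
]

N_DINUCLEOTIDE_PROPERTIES = 6
N_TRINUCLEOTIDE_PROPERTIES = 12

_EXPECTED_N_PROPERTIES = {2: N_DINUCLEOTIDE_PROPERTIES, 3: N_TRINUCLEOTIDE_PROPERTIES}


def _lexicographic_nmers(order: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=order)]


@dataclasses.dataclass
class PropertyTable:
    """Per-n-mer physicochemical values, one column per property.

    ``values`` is indexed by the 4^order n-mers in lexicographic order.
    ``normalized`` records whether min-max normalization has been applied.
    """

    order: int
    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("order must be 2 (dinucleotide) or 3 (trinucleotide)")
        expected = _lexicographic_nmers(self.order)
        if list(self.values.index) != expected:
            missing = sorted(set(expected) - set(self.values.index))
            if missing:
                raise ValueError(f"table missing n-mers: {missing[:5]}...")
            self.values = self.values.loc[expected]
        n_props = _EXPECTED_N_PROPERTIES[self.order]
        if self.values.shape[1] != n_props:
            raise ValueError(
                f"order-{self.order} table must have {n_props} properties, "
                f"got {self.values.shape[1]}"
            )

    @property
    def properties(self) -> list[str]:
        return list(self.values.columns)


def normalize_property_table(table: PropertyTable) -> PropertyTable:
    """Min-max normalize each property column over the 4^n n-mers.

    x -> (x - min) / (max - min), so every column spans exactly [0, 1].
    A constant column leaves the transform undefined and is an error.
    """
    if table.normalized:
        return table
    df = table.values.astype(float)
    lo, hi = df.min(axis=0), df.max(axis=0)
    constant = hi <= lo
    if constant.any():
        bad = list(df.columns[constant])
        raise ValueError(f"constant property column(s), normalization undefined: {bad}")
    return PropertyTable(table.order, (df - lo) / (hi - lo), normalized=True)


def load_property_table(
    path: str | Path, order: int, pre_normalized: bool = False
) -> PropertyTable:
    """Load a tab-separated property table (first column: n-mer, header row:
    property names) and normalize it unless flagged ``pre_normalized``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.str.upper()
    table = PropertyTable(order, df, normalized=pre_normalized)
    if pre_normalized:
        vals = table.values.to_numpy()
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValueError("pre-normalized table has values outside [0, 1]")
        return table
    return normalize_property_table(table)


def _bundled(name: str) -> Path:
    return Path(str(resources.files("dhskit.data").joinpath(name)))


def default_dinucleotide_table() -> PropertyTable:
    """Bundled synthetic dinucleotide table (16 steps x 6 properties), normalized."""
    return load_property_table(
        _bundled("dinucleotide_properties_synthetic.tsv"), order=2
    )


def default_trinucleotide_table() -> PropertyTable:
    """Bundled synthetic trinucleotide table (64 triplets x 12 properties), normalized."""
    return load_property_table(
        _bundled("trinucleotide_properties_synthetic.tsv"), order=3
    )
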
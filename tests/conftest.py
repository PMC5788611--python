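import itertools

import numpy as np
import pandas as pd
import pytest

from dhskit.properties import PropertyTable
from dhskit.seqio import LabeledDataset, SequenceRecord
from dhskit.synthdata import SyntheticSpec, generate


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing FASTA text to a temp file and returning its path."""

    def _write(text, name="test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def toy_dataset():
    """Four short sequences, two per class."""
    records = [
        SequenceRecord("p1", "ACGTACGTAC"),
        SequenceRecord("p2", "GGCCGGCCGG"),
        SequenceRecord("n1", "ATATATATAT"),
        SequenceRecord("n2", "TTAATTAATT"),
    ]
    return LabeledDataset(records, np.array([1, 1, 0, 0], dtype=np.int8))


@pytest.fixture(scope="session")
def small_synthetic():
    """A separable synthetic benchmark small enough for classifier tests."""
    spec = SyntheticSpec(
        n_pos=40, n_neg=60, length_range=(60, 100), gc_pos=0.65, gc_neg=0.35, seed=7
    )
    return generate(spec)


def make_property_table(order, fill=None, normalized=True, n_props=None):
    """Uniform-valued property table; fill maps (property, n-mer) overrides."""
    n_props = n_props or {2: 6, 3: 12}[order]
    nmers = ["".join(p) for p in itertools.product("ACGT", repeat=order)]
    props = [f"prop{i}" for i in range(n_props)]
    df = pd.DataFrame(0.0, index=nmers, columns=props)
    for (prop, nmer), value in (fill or {}).items():
        df.loc[nmer, prop] = value
    return PropertyTable(order, df, normalized=normalized)
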
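import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhskit import encoders
from dhskit.encoders import (
    BLOCK_SIZES,
    EncodingLengthError,
    dpcp,
    encode,
    kmer_composition,
    tpcp,
)
from dhskit.properties import (
    PropertyTable,
    default_dinucleotide_table,
    default_trinucleotide_table,
    normalize_property_table,
)
from dhskit.seqio import LabeledDataset, SequenceRecord

from conftest import make_property_table

dna = st.text(alphabet="ACGT", min_size=5, max_size=60)


class TestKmerComposition:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGT", 1, {"kmer1:A": 0.25, "kmer1:C": 0.25, "kmer1:G": 0.25, "kmer1:T": 0.25}),
            ("AAAA", 2, {"kmer2:AA": 1.0}),
            # 7 overlapping windows: AC,CG,GT,TA,AC,CG,GT
            ("ACGTACGT", 2, {"kmer2:AC": 2 / 7, "kmer2:CG": 2 / 7,
                             "kmer2:GT": 2 / 7, "kmer2:TA": 1 / 7}),
        ],
    )
    def test_worked_examples(self, seq, k, expected):
        vec = kmer_composition(seq, k)
        for name, value in expected.items():
            assert vec[name] == pytest.approx(value)
        others = vec.drop(list(expected))
        assert (others == 0).all()

    def test_pentamer_vector_width(self):
        assert len(kmer_composition("ACGTACGTAC", 5)) == 1024

    def test_too_short_sequence_names_record(self):
        with pytest.raises(EncodingLengthError, match="shorty"):
            kmer_composition(SequenceRecord("shorty", "AC"), 3)

    @given(seq=dna, k=st.integers(1, 5))
    @settings(max_examples=60, deadline=None)
    def test_composition_sums_to_one(self, seq, k):
        assert kmer_composition(seq, k).sum() == pytest.approx(1.0, abs=1e-12)

    @given(seq=dna, k=st.integers(1, 4))
    @settings(max_examples=40, deadline=None)
    def test_self_concatenation_nearly_invariant(self, seq, k):
        """Doubling a sequence changes each k-mer fraction by at most k/L."""
        base = kmer_composition(seq, k)
        doubled = kmer_composition(seq + seq, k)
        assert (doubled - base).abs().max() <= k / len(seq) + 1e-12


class TestPropertyNormalization:
    def test_min_max_formula(self):
        raw = make_property_table(2, normalized=False)
        raw.values.loc[:, :] = 1.0
        raw.values.iloc[0, :] = 2.0
        raw.values.iloc[1, :] = 3.0
        norm = normalize_property_table(raw)
        col = norm.values.iloc[:, 0]
        assert col.iloc[0] == 0.5 and col.iloc[1] == 1.0 and col.iloc[2] == 0.0
        assert col.min() == 0.0 and col.max() == 1.0

    def test_already_unit_interval_column_unchanged(self):
        raw = make_property_table(2, normalized=False)
        raw.values.iloc[0, :] = 1.0  # each column spans exactly [0, 1]
        norm = normalize_property_table(raw)
        pd.testing.assert_frame_equal(norm.values, raw.values.astype(float))

    def test_constant_column_rejected(self):
        raw = make_property_table(2, normalized=False)
        raw.values.loc[:, :] = 5.0
        with pytest.raises(ValueError, match="constant"):
            normalize_property_table(raw)

    @pytest.mark.parametrize(
        "table,n_props",
        [(default_dinucleotide_table(), 6), (default_trinucleotide_table(), 12)],
        ids=["dinucleotide", "trinucleotide"],
    )
    def test_bundled_tables_normalized(self, table, n_props):
        assert len(table.properties) == n_props
        assert np.allclose(table.values.min(axis=0), 0.0)
        assert np.allclose(table.values.max(axis=0), 1.0)

    def test_wrong_property_count_rejected(self):
        with pytest.raises(ValueError, match="6 properties"):
            make_property_table(2, n_props=4)


class TestPhysicochemicalProfiles:
    def test_dpcp_hand_evaluation(self):
        # count(AA)=3 in "AAAA", property value 0.5, N_res=4 -> 3*0.5/4
        table = make_property_table(2, fill={("prop0", "AA"): 0.5})
        vec = dpcp("AAAA", table)
        assert vec["dpcp:prop0:AA"] == pytest.approx(0.375)

    def test_dpcp_absent_dinucleotide_features_zero(self):
        vec = dpcp("AAAA", default_dinucleotide_table())
        assert (vec.filter(like=":GC") == 0).all()
        assert len(vec.filter(like=":GC")) == 6

    def test_dpcp_width(self):
        assert len(dpcp("ACGTACGT")) == 96

    def test_tpcp_hand_evaluation(self):
        # count(AAA)=3 among the 3 windows of "AAAAA", value 0.2, N_res=5
        table = make_property_table(3, fill={("prop0", "AAA"): 0.2})
        vec = tpcp("AAAAA", table)
        assert vec["tpcp:prop0:AAA"] == pytest.approx(0.12)

    def test_tpcp_width(self):
        assert len(tpcp("ACGTACGT")) == 768

    def test_tpcp_too_short(self):
        with pytest.raises(EncodingLengthError):
            tpcp("AC")

    def test_windows_denominator_rescales(self):
        table = make_property_table(2, fill={("prop0", "AA"): 0.5})
        by_length = dpcp("AAAA", table, nres="length")
        by_windows = dpcp("AAAA", table, nres="windows")
        assert by_windows["dpcp:prop0:AA"] == pytest.approx(
            by_length["dpcp:prop0:AA"] * 4 / 3
        )

    @given(seq=dna)
    @settings(max_examples=30, deadline=None)
    def test_profile_values_bounded(self, seq):
        """DPCP/TPCP entries lie in [0, (L-n+1)/L] since counts <= L-n+1."""
        L = len(seq)
        for vec, n in ((dpcp(seq), 2), (tpcp(seq), 3)):
            assert vec.min() >= 0.0
            assert vec.max() <= (L - n + 1) / L + 1e-12


class TestEncode:
    @pytest.mark.parametrize("block,width", list(BLOCK_SIZES.items()))
    def test_single_block_widths(self, toy_dataset, block, width):
        assert encode(toy_dataset, [block]).shape == (4, width)

    def test_full_encoding_is_2228_features(self, toy_dataset):
        X = encode(toy_dataset)
        assert X.shape == (4, 2228)
        assert sum(BLOCK_SIZES.values()) == 2228

    def test_block_concatenation_order_is_canonical(self, toy_dataset):
        X = encode(toy_dataset, ["DPCP", "MNC"])  # request out of order
        assert X.columns[0].startswith("kmer1:")
        assert X.columns[4].startswith("dpcp:")
        assert X.attrs["blocks"] == ["MNC", "DPCP"]

    def test_hybrid_mnc_dnc_is_20_features(self, toy_dataset):
        assert encode(toy_dataset, ["MNC", "DNC"]).shape[1] == 20

    def test_empty_block_list_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="empty block list"):
            encode(toy_dataset, [])

    def test_short_record_error_lists_ids(self):
        ds = LabeledDataset(
            [SequenceRecord("ok", "ACGTACGT"), SequenceRecord("tiny", "ACG")],
            np.array([1, 0], dtype=np.int8),
        )
        with pytest.raises(EncodingLengthError, match="tiny"):
            encode(ds)

    def test_permutation_equivariance(self, small_synthetic):
        ds = small_synthetic
        X = encode(ds, ["MNC", "DNC"])
        perm = np.random.default_rng(0).permutation(len(ds))
        X_perm = encode(ds.subset(perm), ["MNC", "DNC"])
        pd.testing.assert_frame_equal(X.iloc[perm], X_perm)

    def test_rows_match_single_sequence_encoders(self, toy_dataset):
        X = encode(toy_dataset, ["DNC", "DPCP"])
        rec = toy_dataset.records[1]
        expected = pd.concat([kmer_composition(rec, 2), dpcp(rec)])
        assert np.allclose(X.loc[rec.id].to_numpy(), expected.to_numpy())

    def test_feature_names_block_prefixed_and_unique(self, toy_dataset):
        X = encode(toy_dataset)
        assert X.columns.is_unique
        assert set(X.attrs["block_of"].values()) == set(encoders.BLOCK_ORDER)
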
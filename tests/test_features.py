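"""Descriptor encodings against independent explicit-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acpkit import (
    EncoderConfig,
    LabeledDataset,
    PeptideEncoder,
    PeptideRecord,
    encode_aac,
    encode_apaac,
    encode_dataset,
    encode_dpc,
    encode_paac,
    encode_pcp,
)
from acpkit.features import (
    DIPEPTIDES,
    PropertyTable,
    bundled_property_tables,
    read_aaindex1,
    read_feature_matrix,
    write_feature_matrix,
)
from acpkit._property_data import (
    PSEAAC_HYDROPHOBICITY,
    PSEAAC_HYDROPHILICITY,
    PSEAAC_SIDECHAIN_MASS,
)
from acpkit.sequence_io import ACP, CANONICAL_AA, NON_ACP
from conftest import random_peptide

peptides = st.text(alphabet=CANONICAL_AA, min_size=2, max_size=40)


# ------------------------------------------------------------------ oracles
def _std(scale):
    vals = np.array([scale[aa] for aa in CANONICAL_AA])
    return dict(zip(CANONICAL_AA, (vals - vals.mean()) / vals.std()))


H1 = _std(PSEAAC_HYDROPHOBICITY)
H2 = _std(PSEAAC_HYDROPHILICITY)
H3 = _std(PSEAAC_SIDECHAIN_MASS)


def aac_oracle(seq):
    return np.array([seq.count(aa) / len(seq) for aa in CANONICAL_AA])


def dpc_oracle(seq):
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    return np.array([pairs.count(dp) / (len(seq) - 1) for dp in DIPEPTIDES])


def pcp_oracle(seq, tables):
    out = []
    for t in tables:
        std = dict(zip(CANONICAL_AA, t.standardized()))
        out.append(sum(std[aa] for aa in seq) / len(seq))
    return np.array(out)


def paac_oracle(seq, lam, w):
    L = len(seq)
    freqs = [seq.count(aa) / L for aa in CANONICAL_AA]
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j):
            a, b = seq[i], seq[i + j]
            total += ((H1[b] - H1[a]) ** 2 + (H2[b] - H2[a]) ** 2 + (H3[b] - H3[a]) ** 2) / 3
        thetas.append(total / (L - j))
    denom = sum(freqs) + w * sum(thetas)
    return np.array([f / denom for f in freqs] + [w * t / denom for t in thetas])


def apaac_oracle(seq, lam, w):
    L = len(seq)
    freqs = [seq.count(aa) / L for aa in CANONICAL_AA]
    taus = []
    for j in range(1, lam + 1):
        t1 = sum(H1[seq[i]] * H1[seq[i + j]] for i in range(L - j)) / (L - j)
        t2 = sum(H2[seq[i]] * H2[seq[i + j]] for i in range(L - j)) / (L - j)
        taus += [t1, t2]
    denom = sum(freqs) + w * sum(taus)
    return np.array([f / denom for f in freqs] + [w * t / denom for t in taus])


# -------------------------------------------------------------------- tests
class TestAAC:
    def test_homopolymer(self):
        v = encode_aac("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_quarter_each(self):
        v = encode_aac("ACDE")
        assert np.allclose(v[:4], 0.25) and v[4:].sum() == 0.0

    def test_matches_counting_oracle(self, rng):
        seq = random_peptide(rng, 37)
        assert np.allclose(encode_aac(seq), aac_oracle(seq), atol=1e-12)


class TestDPC:
    def test_dimension_is_400(self, rng):
        assert len(encode_dpc(random_peptide(rng, 11))) == 400

    def test_homopolymer_pairs(self):
        v = encode_dpc("AAA")
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_alternating(self):
        v = encode_dpc("ACAC")
        names = dict(zip(DIPEPTIDES, v))
        assert names["AC"] == pytest.approx(2 / 3)
        assert names["CA"] == pytest.approx(1 / 3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            encode_dpc("A")


class TestPCP:
    def test_homopolymer_gives_standardized_value(self):
        tables = bundled_property_tables()
        v = encode_pcp("KKKK", tables)
        expected = [t.standardized()[CANONICAL_AA.index("K")] for t in tables]
        assert np.allclose(v, expected)

    def test_all20_peptide_is_zero(self):
        """A peptide with each residue once averages standardized scales to 0."""
        v = encode_pcp(CANONICAL_AA, bundled_property_tables())
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_matches_averaging_oracle(self, rng):
        seq = random_peptide(rng, 23)
        tables = bundled_property_tables()
        assert np.allclose(encode_pcp(seq, tables), pcp_oracle(seq, tables), atol=1e-12)

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            encode_pcp("KWK", [])


class TestPseAAC:
    def test_lambda_zero_equals_aac(self, rng):
        seq = random_peptide(rng, 15)
        assert np.allclose(encode_paac(seq, 0, 0.05), encode_aac(seq))

    def test_homopolymer_tail_zero(self):
        v = encode_paac("KKKKKK", 3, 0.05)
        assert np.allclose(v[:20], encode_aac("KKKKKK"))
        assert np.allclose(v[20:], 0.0)

    def test_explicit_loop_oracle(self):
        assert np.allclose(
            encode_paac("ACKWL", 2, 0.05), paac_oracle("ACKWL", 2, 0.05), atol=1e-12
        )

    def test_length_constraint_named(self):
        with pytest.raises(ValueError, match="lambda"):
            encode_paac("ACK", 3, 0.05)


class TestAmPseAAC:
    def test_dimension_contract(self, rng):
        for lam in (0, 1, 4):
            seq = random_peptide(rng, 12)
            assert len(encode_apaac(seq, lam, 0.05)) == 20 + 2 * lam

    def test_lambda_zero_equals_aac(self, rng):
        seq = random_peptide(rng, 9)
        assert np.allclose(encode_apaac(seq, 0, 0.05), encode_aac(seq))

    def test_explicit_loop_oracle(self):
        assert np.allclose(
            encode_apaac("GIGKF", 2, 0.05), apaac_oracle("GIGKF", 2, 0.05), atol=1e-12
        )


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seq=peptides)
def test_composition_rows_sum_to_one(seq):
    assert encode_aac(seq).sum() == pytest.approx(1.0, abs=1e-12)
    assert encode_dpc(seq).sum() == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seq=peptides)
def test_pse_encoders_reduce_to_aac_at_lambda_zero(seq):
    aac = encode_aac(seq)
    assert np.allclose(encode_paac(seq, 0, 0.05), aac)
    assert np.allclose(encode_apaac(seq, 0, 0.05), aac)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seq=st.text(alphabet=CANONICAL_AA, min_size=5, max_size=30), lam=st.integers(1, 4))
def test_pse_components_sum_to_one(seq, lam):
    """Both pseudo-composition vectors sum to 1; the type-1 form is also
    non-negative (its correlation factors are squared differences, while the
    amphiphilic tau factors are products and may legitimately be negative)."""
    v = encode_paac(seq, lam, 0.05)
    assert np.all(v >= 0)
    assert v.sum() == pytest.approx(1.0, abs=1e-9)
    w = encode_apaac(seq, lam, 0.05)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)


def test_permutation_leaves_aac_changes_dpc(rng):
    seq = "KWKLFKKIGAVLKVL"
    perm = "".join(rng.permutation(list(seq)))
    assert np.allclose(encode_aac(seq), encode_aac(perm))
    assert not np.allclose(encode_dpc(seq), encode_dpc("KW" + seq[2:][::-1]))


def test_encoders_deterministic(rng):
    seq = random_peptide(rng, 33)
    for enc in (lambda s: encode_paac(s, 5, 0.05), lambda s: encode_apaac(s, 5, 0.05)):
        a, b = enc(seq), enc(seq)
        assert np.array_equal(a, b)


class TestEncodeDataset:
    def test_dimension_sum(self, small_dataset):
        X = encode_dataset(
            small_dataset, EncoderConfig(encoders=("AAC", "AmPseAAC"), lambda_=3)
        )
        assert X.shape == (len(small_dataset), 46)

    def test_blockwise_equality(self, small_dataset):
        config = EncoderConfig(encoders=("AAC", "PseAAC"), lambda_=4, weight=0.1)
        X = encode_dataset(small_dataset, config)
        for i, rec in enumerate(small_dataset.records[:5]):
            np.testing.assert_allclose(X.iloc[i, :20], encode_aac(rec.sequence))
            np.testing.assert_allclose(
                X.iloc[i, 20:], encode_paac(rec.sequence, 4, 0.1)
            )

    def test_error_names_sequence(self):
        ds = LabeledDataset(
            [PeptideRecord("okpep", "KWKLFKKILK"), PeptideRecord("shorty", "KW")],
            [ACP, NON_ACP],
        )
        with pytest.raises(ValueError, match="shorty"):
            encode_dataset(ds, EncoderConfig(encoders=("PseAAC",), lambda_=5))

    def test_csv_roundtrip(self, small_dataset, tmp_path):
        X = encode_dataset(small_dataset, EncoderConfig(encoders=("AAC",)))
        write_feature_matrix(X, tmp_path / "fm.csv")
        back = read_feature_matrix(tmp_path / "fm.csv")
        assert list(back.columns) == list(X.columns)
        np.testing.assert_allclose(back.to_numpy(), X.to_numpy(), atol=1e-12)


class TestPeptideEncoder:
    def test_sklearn_contract(self, small_dataset):
        enc = PeptideEncoder(encoders=("AAC",))
        params = enc.get_params()
        assert params["encoders"] == ("AAC",)
        X = enc.fit_transform(small_dataset.sequences)
        assert list(enc.get_feature_names_out()) == list(X.columns)

    def test_works_in_pipeline(self, small_dataset):
        from sklearn.pipeline import Pipeline
        from sklearn.linear_model import LogisticRegression

        pipe = Pipeline(
            [("encode", PeptideEncoder(encoders=("AAC",))),
             ("clf", LogisticRegression(max_iter=500))]
        )
        pipe.fit(small_dataset.sequences, small_dataset.labels)
        assert pipe.score(small_dataset.sequences, small_dataset.labels) > 0.8


class TestPropertyTables:
    def test_standardized_mean_sd(self):
        for t in bundled_property_tables():
            z = t.standardized()
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_missing_residue_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PropertyTable("X", "bad", {"A": 1.0})

    def test_aaindex1_parser(self, tmp_path):
        flat = (
            "H TEST000101\n"
            "D A synthetic test scale\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
            "     1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0\n"
            "    11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0\n"
            "//\n"
            "H TEST000102\n"
            "D A scale with a missing value\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
            "     1.0     2.0     3.0     4.0      NA     6.0     7.0     8.0     9.0    10.0\n"
            "    11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0\n"
            "//\n"
        )
        path = tmp_path / "aaindex1"
        path.write_text(flat)
        tables = read_aaindex1(path)
        assert [t.accession for t in tables] == ["TEST000101"]
        assert tables[0].values["A"] == 1.0
        assert tables[0].values["L"] == 11.0
        assert tables[0].values["V"] == 20.0
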
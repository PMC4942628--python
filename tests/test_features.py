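import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lypred.errors import AlignmentError, SequenceTooShortError
from lypred.features import (
    FeatureMatrix,
    PseAACParams,
    correlation_factors,
    encode,
    encode_matrix,
    feature_names,
    gap_dipeptide_frequencies,
)
from lypred.seqio import AMINO_ACIDS, ProteinRecord

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


# --- independent brute-force oracles: naive nested loops ----------------


def brute_dipeptide(seq, g):
    counts = np.zeros(400)
    for t in range(len(seq) - g - 1):
        counts[20 * AA_INDEX[seq[t]] + AA_INDEX[seq[t + g + 1]]] += 1
    return counts / (len(seq) - g - 1)


def brute_correlation(seq, delta, rho):
    out = []
    for d in range(1, delta + 1):
        for j in range(rho.shape[0]):
            total = 0.0
            for t in range(len(seq) - d):
                total += rho[j, AA_INDEX[seq[t]]] * rho[j, AA_INDEX[seq[t + d]]]
            out.append(total / (len(seq) - d))
    return np.array(out)


sequences = st.text(alphabet=AMINO_ACIDS, min_size=12, max_size=60)


class TestGapDipeptides:
    def test_homopolymer(self):
        v = gap_dipeptide_frequencies("AAAA", g=0)
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_alternating_sequence_gap1(self):
        # pairs at offset 2: AA, CC, AA, CC over denominator 4
        v = gap_dipeptide_frequencies("ACACAC", g=1)
        assert v[20 * AA_INDEX["A"] + AA_INDEX["A"]] == 0.5
        assert v[20 * AA_INDEX["C"] + AA_INDEX["C"]] == 0.5
        assert v.sum() == 1.0

    @pytest.mark.parametrize("g", range(10))
    def test_matches_brute_force(self, g, rng, random_records):
        rec = random_records(1, lo=60, hi=60)[0]
        assert np.allclose(
            gap_dipeptide_frequencies(rec, g), brute_dipeptide(rec.sequence, g),
            atol=1e-15,
        )

    def test_too_short(self):
        with pytest.raises(SequenceTooShortError, match="5"):
            gap_dipeptide_frequencies("ACDEF", g=4)

    @settings(max_examples=40, derandomize=True)
    @given(seq=sequences, g=st.integers(0, 9))
    def test_block_sums_to_one(self, seq, g):
        assert gap_dipeptide_frequencies(seq, g).sum() == pytest.approx(1.0, abs=1e-9)


class TestCorrelationFactors:
    def test_homopolymer_equals_rho_squared(self, table):
        out = correlation_factors("AAAAAAAA", delta=3, table=table)
        rho_a = table.normalized[:, AA_INDEX["A"]]
        assert np.allclose(out, np.tile(rho_a**2, 3), atol=1e-12)

    def test_single_term_average(self, table):
        out = correlation_factors("AC", delta=1, table=table, property_subset=(0,))
        expected = table.normalized[0, AA_INDEX["A"]] * table.normalized[0, AA_INDEX["C"]]
        assert out[0] == pytest.approx(expected, abs=1e-15)

    def test_matches_brute_force_40mer(self, table, random_records):
        rec = random_records(1, lo=40, hi=40)[0]
        out = correlation_factors(rec, delta=7, table=table)
        assert out.shape == (63,)
        assert np.allclose(out, brute_correlation(rec.sequence, 7, table.normalized), atol=1e-12)

    def test_reversal_invariance(self, table, random_records):
        rec = random_records(1, lo=50, hi=50)[0]
        fwd = correlation_factors(rec.sequence, delta=5, table=table)
        rev = correlation_factors(rec.sequence[::-1], delta=5, table=table)
        assert np.allclose(fwd, rev, atol=1e-12)

    def test_too_short(self, table):
        with pytest.raises(SequenceTooShortError):
            correlation_factors("ACDEF", delta=5, table=table)


class TestEncode:
    def test_dimension_463(self, table, random_records):
        rec = random_records(1, lo=30, hi=30)[0]
        vec = encode(rec, PseAACParams(g=4, delta=7), table)
        assert len(vec.values) == 463 and len(vec.names) == 463

    def test_small_param_hand_example(self, table):
        # g=0, delta=1, hydrophobicity only, on ACAC
        rec = ProteinRecord("x", "ACAC")
        vec = encode(rec, PseAACParams(g=0, delta=1, property_subset=(0,)), table)
        assert len(vec.values) == 401
        assert np.allclose(vec.values[:400], brute_dipeptide("ACAC", 0), atol=1e-15)
        ra = table.normalized[0, AA_INDEX["A"]]
        rc = table.normalized[0, AA_INDEX["C"]]
        assert vec.values[400] == pytest.approx((ra * rc + rc * ra + ra * rc) / 3, abs=1e-14)

    def test_boundary_length_error(self, table):
        rec = ProteinRecord("x", "ACDEF")  # L=5, g=4 needs L>=6
        with pytest.raises(SequenceTooShortError):
            encode(rec, PseAACParams(g=4, delta=1), table)

    def test_lag_major_prefix_structure(self, table, random_records):
        # smaller delta vectors are prefixes of larger ones (lag-major layout)
        rec = random_records(1, lo=40, hi=40)[0]
        small = correlation_factors(rec, delta=3, table=table)
        big = correlation_factors(rec, delta=10, table=table)
        assert np.array_equal(big[: len(small)], small)

    def test_permutation_changes_correlation_not_g0_marginal(self, table):
        seq = "ACDEFGHIKLMNPQRSTVWYAC"
        perm = "CAKLHGFEDIMNPQRSTVWYCA"  # same multiset of residues
        assert sorted(seq) == sorted(perm)
        c1 = correlation_factors(seq, delta=3, table=table)
        c2 = correlation_factors(perm, delta=3, table=table)
        assert not np.allclose(c1, c2)

    def test_names_match_convention(self, table):
        names = feature_names(PseAACParams(g=2, delta=2, property_subset=(0, 6)), table)
        assert names[0] == "dipeptide:AA:gap2"
        assert names[399] == "dipeptide:YY:gap2"
        assert names[400] == "corr:hydrophobicity:lag1"
        assert names[401] == "corr:pI:lag1"
        assert names[-1] == "corr:pI:lag2"

    def test_out_of_grid_params_warn(self):
        with pytest.warns(UserWarning):
            PseAACParams(g=12, delta=1)


class TestEncodeMatrix:
    def test_shape_and_labels(self, table, random_records):
        recs = random_records(3, lo=20, hi=30)
        labels = {r.id: i % 2 for i, r in enumerate(recs)}
        m = encode_matrix(recs, labels, PseAACParams(g=0, delta=1), table)
        assert m.X.shape == (3, 409)
        assert list(m.y) == [0, 1, 0]
        assert m.ids == [r.id for r in recs]

    def test_empty_records(self, table):
        m = encode_matrix([], {}, PseAACParams(g=0, delta=1), table)
        assert m.X.shape == (0, 409) and len(m.X.columns) == 409

    def test_duplicate_ids_rejected(self, table):
        recs = [ProteinRecord("a", "ACDEFGHIKL"), ProteinRecord("a", "MKLVWYTREA")]
        with pytest.raises(AlignmentError, match="duplicate"):
            encode_matrix(recs, {"a": 1}, PseAACParams(g=0, delta=1), table)

    def test_missing_label_rejected(self, table):
        recs = [ProteinRecord("a", "ACDEFGHIKL")]
        with pytest.raises(AlignmentError, match="a"):
            encode_matrix(recs, {}, PseAACParams(g=0, delta=1), table)

    def test_tsv_round_trip(self, table, random_records, tmp_path):
        recs = random_records(4, lo=20, hi=30)
        labels = {r.id: i % 2 for i, r in enumerate(recs)}
        m = encode_matrix(recs, labels, PseAACParams(g=1, delta=2), table)
        path = tmp_path / "features.tsv"
        m.to_tsv(path)
        again = FeatureMatrix.from_tsv(path)
        assert list(again.X.columns) == list(m.X.columns)
        assert np.allclose(again.X.to_numpy(), m.X.to_numpy(), atol=1e-12)
        assert np.array_equal(again.y, m.y)
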
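"""Charge tables and the sliding electrostatic complementarity score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdr3comp import (ChargeTable, ScoreWeights, alignment_score, pair_score,
                      residue_charge, score_matrix, CDR3Peptide, AntigenFragment)
from cdr3comp.exceptions import AlphabetError, ValidationError

from .conftest import SCORING_ALPHABET, random_peptide
from .oracle import brute_pair_score, brute_alignment_score

seqs = st.text(alphabet=SCORING_ALPHABET, min_size=5, max_size=12)
keg_seqs = st.text(alphabet="KEG", min_size=1, max_size=12)


class TestChargeTable:
    @pytest.mark.parametrize("aa,expected", [
        ("K", 1.0), ("R", 1.0), ("H", 0.5), ("D", -1.0), ("E", -1.0),
        ("G", 0.0), ("A", 0.0), ("W", 0.0),
    ])
    def test_default_charges(self, aa, expected):
        assert residue_charge(aa) == expected

    @pytest.mark.parametrize("bad", list("BJOUXZ*"))
    def test_nonstandard_letters_rejected_not_zeroed(self, bad):
        with pytest.raises(AlphabetError) as exc:
            residue_charge(bad)
        assert bad in str(exc.value)

    def test_out_of_range_charge_rejected(self):
        with pytest.raises(ValidationError):
            ChargeTable.with_overrides(K=2.0)

    def test_missing_residue_rejected(self):
        with pytest.raises(ValidationError):
            ChargeTable({"K": 1.0})

    def test_overrides(self):
        table = ChargeTable.with_overrides(H=1.0)
        assert residue_charge("H", table) == 1.0
        assert residue_charge("K", table) == 1.0


class TestAlignmentScore:
    def test_opposite_charges_add(self):
        # direct terms 3x1.0, in-range neighbour terms 4x0.5
        assert alignment_score("KKK", "EEE", 0) == pytest.approx(5.0)

    def test_like_charges_subtract(self):
        assert alignment_score("KKK", "KKK", 0) == pytest.approx(-5.0)

    def test_neutral_slider_scores_zero(self):
        assert alignment_score("GGG", "KEDRH", 1) == 0.0

    def test_offset_out_of_range(self):
        with pytest.raises(ValidationError):
            alignment_score("KKK", "EEE", 1)

    def test_longer_cdr3_directs_to_pair_score(self):
        with pytest.raises(ValidationError, match="pair_score"):
            alignment_score("KKKKK", "EEE", 0)

    def test_equal_length_antisymmetry_under_charge_negation(self, rng):
        """phi is bilinear: replacing the antigen by its charge-negated
        counterpart flips the sign of the fixed-register score."""
        flip = str.maketrans("KRDE", "EDRK")
        for _ in range(500):
            seq = random_peptide(rng, int(rng.integers(5, 13)), "KRDEGA")
            other = random_peptide(rng, len(seq), "KRDEGA")
            flipped = other.translate(flip)
            assert alignment_score(seq, flipped, 0) == pytest.approx(
                -alignment_score(seq, other, 0)
            )


class TestPairScore:
    def test_best_register_found(self):
        # brute force over all 5 offsets: maximum at the register on EEE
        assert pair_score("KKK", "GGEEEGG") == pytest.approx(5.0)

    def test_neutral_sequence_scores_zero_anywhere(self):
        assert pair_score("GGGGG", "KRHDEKRHDE") == 0.0

    def test_two_residue_pair_hand_oracle(self):
        # exhaustive offset enumeration by hand: single register,
        # direct +1 +1, adjacent -0.5 -0.5
        assert pair_score("KE", "EK") == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            pair_score("", "KKK")

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(300):
            a = random_peptide(rng, int(rng.integers(5, 13)))
            b = random_peptide(rng, int(rng.integers(5, 13)))
            assert pair_score(a, b) == pytest.approx(brute_pair_score(a, b), abs=1e-12)

    @given(a=keg_seqs, b=keg_seqs)
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence_exhaustive_small(self, a, b):
        """Exact agreement with the brute-force oracle over {K,E,G}."""
        assert pair_score(a, b) == pytest.approx(brute_pair_score(a, b), abs=0)

    @given(a=seqs, b=seqs)
    @settings(max_examples=300, deadline=None)
    def test_role_symmetry(self, a, b):
        """The shorter sequence slides along the longer, so argument order
        cannot matter."""
        assert pair_score(a, b) == pytest.approx(pair_score(b, a))

    @given(seq=st.text(alphabet="KRHDEGA", min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_neutrality(self, seq):
        """All-neutral sequences annihilate every charge product."""
        assert pair_score("GAGAG", seq) == 0.0

    def test_monotonicity_appending_opposite_pair(self, rng):
        """Appending an oppositely charged residue pair at aligned positions
        never decreases the fixed-register score (holds for the default
        weights, where w_direct >= 2*w_adjacent)."""
        pairs = [("K", "E"), ("E", "K"), ("R", "D"), ("D", "R")]
        for _ in range(500):
            n = int(rng.integers(1, 10))
            a = random_peptide(rng, n, "KRDEGA")
            b = random_peptide(rng, n, "KRDEGA")
            x, y = pairs[int(rng.integers(0, len(pairs)))]
            before = brute_alignment_score(a, b, 0)
            after = brute_alignment_score(a + x, b + y, 0)
            assert after >= before - 1e-12

    def test_normalization_flag(self):
        assert pair_score("KKK", "EEE", normalize=True) == pytest.approx(5.0 / 3)

    def test_custom_weights(self):
        w = ScoreWeights(w_direct=2.0, w_adjacent=0.0)
        assert pair_score("KKK", "EEE", weights=w) == pytest.approx(6.0)

    def test_adjacent_weight_cannot_exceed_direct(self):
        with pytest.raises(ValidationError):
            ScoreWeights(w_direct=0.5, w_adjacent=1.0)


class TestScoreMatrix:
    def test_singleton_consistency(self, make_cdr3, make_fragment):
        c = make_cdr3("CKKKEF")
        f = make_fragment("GGEEEGG")
        m = score_matrix([c], [f])
        assert m.shape == (1, 1)
        assert m.iloc[0, 0] == pytest.approx(pair_score(c, f))
        assert m.index[0] == "case1:TRB:CKKKEF"
        assert m.columns[0] == "AG:1"

    def test_neutral_rows_all_zero(self, make_cdr3, make_fragment):
        cs = [make_cdr3("GAGAG", case_id=f"c{i}") for i in range(3)]
        fs = [make_fragment("KRHDE", index=i + 1) for i in range(2)]
        assert (score_matrix(cs, fs).to_numpy() == 0).all()

    def test_matches_elementwise_oracle(self, rng, make_cdr3, make_fragment):
        cs = [make_cdr3(random_peptide(rng, int(rng.integers(5, 13))), case_id=f"c{i}")
              for i in range(5)]
        fs = [make_fragment(random_peptide(rng, int(rng.integers(5, 13))), index=j + 1)
              for j in range(4)]
        m = score_matrix(cs, fs)
        for i, c in enumerate(cs):
            for j, f in enumerate(fs):
                assert m.iloc[i, j] == pytest.approx(
                    brute_pair_score(c.sequence, f.sequence), abs=1e-12)

    def test_empty_inputs_rejected(self, make_cdr3):
        with pytest.raises(ValidationError):
            score_matrix([], [])


class TestDomainTypes:
    def test_short_cdr3_rejected(self):
        with pytest.raises(ValidationError):
            CDR3Peptide("c1", "TRB", "CAF")

    def test_bad_chain_rejected(self):
        with pytest.raises(ValidationError):
            CDR3Peptide("c1", "TRG", "CASSF")

    def test_nonstandard_letter_rejected_with_position(self):
        with pytest.raises(AlphabetError, match="position 2"):
            CDR3Peptide("c1", "TRB", "CAXSF")

    def test_fragment_index_zero_means_whole_protein(self):
        frag = AntigenFragment("SPAG9", 0, "KHIEV")
        assert frag.label == "SPAG9:0"
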
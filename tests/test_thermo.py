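"""Folding-engine tests: structure evaluation, MFE search, duplexes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptatrigger import (
    DotBracketStructure,
    NucleicSequence,
    SequenceError,
    duplex_mfe,
    energy_of_structure,
    enumerate_structures,
    fold_mfe,
    fold_with_aptamer_bonus,
)
from aptatrigger.thermo import fold_constrained_pair

rna = st.text(alphabet="ACGU", min_size=8, max_size=14)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGU"), n))


class TestEnergyOfStructure:
    def test_open_chain_is_energy_zero(self):
        assert energy_of_structure("ACGUACGUA", ".........") == 0.0

    def test_cg_helix_with_tetraloop_matches_hand_sum(self):
        # three GC/GC stacks (-3.26 each) + hairpin-4 initiation (+5.60),
        # no terminal penalty on a G:C closing pair
        e = energy_of_structure("GGGGAAAACCCC", "((((....))))")
        assert e == pytest.approx(3 * -3.26 + 5.60, abs=1e-9)

    def test_consistent_with_mfe_search(self):
        r = fold_mfe("GGCGAAAGCGCCAAAGGCGC")
        assert energy_of_structure(r.sequence, r.structure) == r.dg

    @pytest.mark.parametrize(
        "seq, db, message",
        [
            ("ACGA", "(..)", "invalid pair"),
            ("GAAC", "(..)", "hairpin loop"),
            ("ACGU", ".....", "length"),
        ],
    )
    def test_invalid_structures_rejected(self, seq, db, message):
        with pytest.raises(SequenceError, match=message):
            energy_of_structure(seq, db)


class TestFoldMfe:
    def test_unpairable_sequence_is_open_chain(self):
        r = fold_mfe("AAAAAAA")
        assert r.structure.db == "......." and r.dg == 0.0

    def test_dna_input_equals_rna_transliteration(self):
        assert fold_mfe("GGGGAAAATTTT") == fold_mfe("GGGGAAAAUUUU")

    def test_never_positive_energy(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            assert fold_mfe(random_seq(rng, int(rng.integers(5, 40)))).dg <= 0.0

    def test_deterministic_repeat_calls(self):
        seq = "GGCAGAUCUGAGCCUGGGAGCUCUCUGGC"
        a, b = fold_mfe(seq), fold_mfe(seq)
        assert a.structure.db == b.structure.db and a.dg == b.dg

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(rna)
    def test_matches_enumeration_oracle(self, seq):
        es = enumerate_structures(seq)
        r = fold_mfe(seq)
        assert r.dg == min(e for _, e in es)
        assert energy_of_structure(seq, r.structure) == r.dg

    def test_rank_agreement_with_independent_predictor(self):
        # different parameter details (no dangles/coaxial terms here), so
        # only the ordering of stabilities is compared
        import RNA
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        mine, theirs = [], []
        for _ in range(40):
            seq = random_seq(rng, 40)
            mine.append(fold_mfe(seq).dg)
            theirs.append(RNA.fold(seq)[1])
        assert spearmanr(mine, theirs).statistic > 0.8


class TestEnumeration:
    def test_min_hairpin_forbids_all_pairs(self):
        es = enumerate_structures("AAAA")
        assert len(es) == 1 and es[0][0].db == "...." and es[0][1] == 0.0

    def test_count_matches_independent_recursion(self):
        seq = "GGGAAACCC"
        s = NucleicSequence("s", seq).encode()
        from aptatrigger.params import PAIR_INDEX

        def count(i, j, memo={}):
            if i >= j:
                return 1
            key = (i, j, seq)
            if key not in memo:
                total = count(i + 1, j)
                for k in range(i + 4, j + 1):
                    if PAIR_INDEX[s[i], s[k]] >= 0:
                        total += count(i + 1, k - 1) * count(k + 1, j)
                memo[key] = total
            return memo[key]

        assert len(enumerate_structures(seq)) == count(0, len(seq) - 1)

    def test_refuses_long_sequences(self):
        with pytest.raises(ValueError, match="max_len"):
            enumerate_structures("ACGU" * 8)


class TestDuplex:
    def test_no_complementarity_gives_zero(self):
        assert duplex_mfe("AAAA", "AAAA") == (0.0, {})

    def test_weak_au_duplex_is_unfavorable(self):
        # 3 AU/AU stacks (-2.79) never beat initiation (+4.09) plus two
        # AU-end penalties: no favorable duplex exists
        assert duplex_mfe("AAAA", "UUUU") == (0.0, {})

    def test_perfect_duplex_matches_hand_sum(self):
        # stacks AU/CG (-2.24), CG/GC (-2.36), GC/CG (-3.42), CG/AU (-2.11)
        # + initiation 4.09 + two AU-end penalties
        e, pairs = duplex_mfe("ACGCA", "UGCGU")
        assert e == pytest.approx(-2.24 - 2.36 - 3.42 - 2.11 + 4.09 + 1.0, abs=1e-9)
        assert pairs == {0: 4, 1: 3, 2: 2, 3: 1, 4: 0}

    def test_symmetric_in_strand_order(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = random_seq(rng, int(rng.integers(6, 20)))
            b = random_seq(rng, int(rng.integers(6, 20)))
            assert duplex_mfe(a, b)[0] == duplex_mfe(b, a)[0]

    def test_perfect_complement_beats_shuffle(self):
        from aptatrigger.sequence import reverse_complement

        rng = np.random.default_rng(19)
        stronger = 0
        for _ in range(50):
            a = random_seq(rng, 10)
            b = reverse_complement(a)
            shuffled = "".join(rng.permutation(list(b)))
            if duplex_mfe(a, b)[0] < duplex_mfe(a, shuffled)[0]:
                stronger += 1
        assert stronger == 50


class TestAptamerBonus:
    SEQ = "GGGAGAAAUCCCAAAGGGAAAUCUCCC"

    def test_zero_bonus_identical_to_plain_fold(self):
        r0 = fold_with_aptamer_bonus(self.SEQ, (0, len(self.SEQ)), 0.0)
        r = fold_mfe(self.SEQ)
        assert r0.structure.db == r.structure.db and r0.dg == r.dg

    def test_dominating_bonus_forces_closing_pair(self):
        r = fold_with_aptamer_bonus(self.SEQ, (0, len(self.SEQ)), -100.0)
        assert r.bonus_applied
        pt = r.structure.pair_table()
        assert pt[0] == len(self.SEQ) - 1

    def test_energy_non_increasing_in_bonus_magnitude(self):
        prev = 0.0
        for b in range(0, 11):
            dg = fold_with_aptamer_bonus(self.SEQ, (3, 20), -float(b)).dg
            assert dg <= prev + 1e-12
            prev = dg

    def test_positive_bonus_rejected(self):
        with pytest.raises(ValueError, match="<= 0"):
            fold_with_aptamer_bonus(self.SEQ, (0, 5), 1.0)

    def test_out_of_bounds_span_rejected(self):
        with pytest.raises(SequenceError, match="out of bounds"):
            fold_with_aptamer_bonus(self.SEQ, (0, 99), -1.0)

    def test_constrained_fold_energy_excludes_bonus(self):
        forced = fold_constrained_pair(self.SEQ, 0, len(self.SEQ) - 1)
        assert forced is not None
        assert forced.dg == energy_of_structure(self.SEQ, forced.structure)
        assert forced.dg >= fold_mfe(self.SEQ).dg

    def test_constrained_fold_impossible_pair_is_none(self):
        assert fold_constrained_pair("AAAAAAAA", 0, 7) is None
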
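"""Apta-trigger assembly, ddG scoring and design-variant tests."""

import numpy as np
import pytest

from aptatrigger import fold_mfe
from aptatrigger.design import (
    OPTIMAL,
    TOO_STRONG,
    TOO_WEAK,
    assemble_apta_trigger,
    classify_stability,
    compute_ddg,
    enumerate_stem_variants,
    insertion_position_variants,
    make_cis_construct,
    parse_design_name,
    trim_partial_triggers,
)
from aptatrigger.parts import generate_toy_aptamer, load_aptamer
from aptatrigger.sequence import SequenceError


def gc_pairs(v):
    return sum(
        1 for k in range(len(v.stem5))
        if {v.stem5[k], v.stem3[len(v.stem3) - 1 - k]} == {"G", "C"}
    )


class TestComputeDdg:
    def test_self_comparison_is_zero(self, theophylline):
        for name in ("theophylline", "tetracycline", "ms2_hairpin"):
            apt = load_aptamer(name)
            assert compute_ddg(apt, apt).ddg == 0.0

    def test_weaker_arm_scores_higher_ddg(self, theophylline):
        # the A2-style UAUG arm destabilizes relative to the A1 GGUG arm
        uaug = compute_ddg(theophylline.with_stem("UAUG"), theophylline)
        assert uaug.ddg > 0.0
        uauu = compute_ddg(theophylline.with_stem("UAUU"), theophylline)
        assert uauu.ddg > uaug.ddg

    def test_different_cores_rejected(self, theophylline):
        ms2 = load_aptamer("ms2_hairpin")
        with pytest.raises(SequenceError, match="different cores"):
            compute_ddg(ms2, theophylline)

    def test_removing_a_closing_pair_never_stabilizes(self):
        rng = np.random.default_rng(13)
        checked = 0
        for seed in range(20):
            apt = generate_toy_aptamer(100 + seed, stem_len=int(rng.integers(3, 6)))
            truncated = apt.with_stem(apt.stem5[1:], apt.stem3[:-1])
            sv = compute_ddg(truncated, apt)
            assert sv.ddg >= -1e-9
            checked += 1
        assert checked == 20


class TestClassifyStability:
    @pytest.mark.parametrize(
        "ddg, expected",
        [(-1.0, TOO_STRONG), (3.0, TOO_STRONG), (3.001, OPTIMAL),
         (5.0, OPTIMAL), (6.999, OPTIMAL), (7.0, TOO_WEAK), (10.0, TOO_WEAK)],
    )
    def test_window_boundaries(self, ddg, expected):
        assert classify_stability(ddg) == expected

    def test_classes_partition_the_line(self):
        rng = np.random.default_rng(1)
        for ddg in rng.uniform(-20, 20, 200):
            assert classify_stability(float(ddg)) in (TOO_STRONG, OPTIMAL, TOO_WEAK)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            classify_stability(1.0, window=(5.0, 3.0))


class TestEnumerateStemVariants:
    def test_single_position_has_six_pair_types(self, theophylline):
        vs = enumerate_stem_variants(theophylline, {1})
        assert len(vs) == 6
        assert sorted(v.stem5 for v in vs) == ["A", "C", "G", "G", "U", "U"]

    def test_sorted_by_ddg(self, theophylline):
        vs = enumerate_stem_variants(theophylline, {2})
        assert all(vs[i].ddg <= vs[i + 1].ddg for i in range(len(vs) - 1))

    def test_sampling_cap_and_determinism(self, theophylline):
        a = enumerate_stem_variants(theophylline, {4}, max_variants=50, seed=3)
        b = enumerate_stem_variants(theophylline, {4}, max_variants=50, seed=3)
        assert len(a) == 50 and a == b

    def test_gc_rich_stems_most_stabilizing_at_length_4(self, theophylline):
        # global MFE refolding lets arms pair the core, so the ordering is
        # a trend: the minimizer is GC-rich and the all-GC class has the
        # lowest median ddG
        vs = enumerate_stem_variants(theophylline, {4})
        assert gc_pairs(vs[0]) >= 3
        medians = {}
        for v in vs:
            medians.setdefault(gc_pairs(v), []).append(v.ddg)
        med = {g: float(np.median(d)) for g, d in medians.items()}
        assert med[4] == min(med.values())

    def test_empty_lengths_rejected(self, theophylline):
        with pytest.raises(ValueError, match="non-empty"):
            enumerate_stem_variants(theophylline, set())


class TestAssembly:
    def test_domain_concatenation_lengths(self, start_set):
        switch, pair, apt = start_set[0]
        d = assemble_apta_trigger(pair, apt, linker_len=3)
        expected = (len(pair.b_star) + len(pair.a_star)
                    + len(apt.sequence) + 2 * 3)
        assert len(d.full_sequence) == expected
        assert d.full_sequence.bases == (
            pair.b_star + "AAA" + apt.sequence.bases + "AAA" + pair.a_star
        )

    def test_unmodified_stem_scores_zero(self, start_set):
        _, pair, apt = start_set[0]
        d = assemble_apta_trigger(pair, apt)
        assert d.ddg == 0.0

    def test_deterministic(self, start_set):
        _, pair, apt = start_set[0]
        assert assemble_apta_trigger(pair, apt) == assemble_apta_trigger(pair, apt)

    def test_name_round_trip(self, start_set):
        _, pair, apt = start_set[1]
        d = assemble_apta_trigger(pair, apt, switch_id="B", version=3)
        ligand, switch_id, version = parse_design_name(d.name)
        assert (switch_id, version) == ("B", 3)
        assert apt.ligand.lower().startswith(ligand.lower()[:4])


class TestTrimming:
    def test_zero_trim_is_identity(self, toy_designs):
        d = toy_designs[0]
        assert trim_partial_triggers(d, 0, 0) is d

    def test_trim_removes_outer_ends_and_preserves_original(self, toy_designs):
        d = toy_designs[0]
        t = trim_partial_triggers(d, 2, 3)
        assert t.b_star == d.b_star[2:]
        assert t.a_star == d.a_star[:-3]
        assert d.b_star != t.b_star  # original untouched
        assert t.aptamer_variant == d.aptamer_variant

    def test_over_trimming_rejected(self, toy_designs):
        d = toy_designs[0]
        with pytest.raises(SequenceError, match="over-trimming"):
            trim_partial_triggers(d, len(d.b_star), 0)

    def test_trimming_reduces_predicted_leak(self, start_set, toy_designs):
        from aptatrigger.circuit import predict_leak

        for (switch, _, _), d in zip(start_set, toy_designs):
            base = predict_leak(d, switch)
            for n5, n3 in ((1, 0), (0, 1), (2, 2), (3, 3)):
                trimmed = trim_partial_triggers(d, n5, n3)
                assert predict_leak(trimmed, switch) <= base + 1e-12


class TestInsertionPositions:
    def test_canonical_split_matches_direct_assembly(self, start_set):
        _, pair, apt = start_set[0]
        direct = assemble_apta_trigger(pair, apt)
        via = insertion_position_variants(pair, apt, positions=[len(pair.b_star)])
        assert via[0].full_sequence.bases == direct.full_sequence.bases

    def test_one_design_per_position_with_unique_names(self, start_set):
        _, pair, apt = start_set[0]
        mid = len(pair.full_trigger) // 2
        designs = insertion_position_variants(pair, apt, positions=[mid - 2, mid, mid + 2])
        assert len(designs) == 3
        assert len({d.name for d in designs}) == 3

    def test_split_point_does_not_alter_ddg(self, start_set):
        _, pair, apt = start_set[0]
        mid = len(pair.full_trigger) // 2
        designs = insertion_position_variants(pair, apt, positions=[mid - 2, mid, mid + 2])
        assert len({d.ddg for d in designs}) == 1

    def test_empty_domain_split_rejected(self, start_set):
        _, pair, apt = start_set[0]
        with pytest.raises(SequenceError, match="empty partial trigger"):
            insertion_position_variants(pair, apt, positions=[0])


class TestCisConstruct:
    def test_length_arithmetic(self, start_set, toy_designs):
        switch, _, _ = start_set[0]
        d = toy_designs[0]
        cis = make_cis_construct(d, switch, tether_len=7)
        assert len(cis) == len(d.full_sequence) + 7 + len(switch.sequence)

    def test_tether_unpaired_in_mfe(self, start_set, toy_designs):
        switch, _, _ = start_set[0]
        d = toy_designs[0]
        cis = make_cis_construct(d, switch)
        start = len(d.full_sequence)
        db = fold_mfe(cis).structure.db
        assert set(db[start:start + 7]) == {"."}

    def test_zero_tether_direct_fusion(self, start_set, toy_designs):
        switch, _, _ = start_set[0]
        d = toy_designs[0]
        cis = make_cis_construct(d, switch, tether_len=0)
        assert cis.bases == d.full_sequence.bases + switch.sequence.bases

    def test_non_cognate_pair_rejected(self, start_set, toy_designs):
        other_switch = start_set[1][0]
        with pytest.raises(SequenceError, match="not cognate"):
            make_cis_construct(toy_designs[0], other_switch)

    def test_trimmed_design_still_cognate(self, start_set, toy_designs):
        switch, _, _ = start_set[0]
        trimmed = trim_partial_triggers(toy_designs[0], 2, 2)
        cis = make_cis_construct(trimmed, switch)
        assert len(cis) == len(trimmed.full_sequence) + 7 + len(switch.sequence)
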
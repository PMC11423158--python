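"""Activation scoring, crosstalk and logic-gate tests."""

import numpy as np
import pytest

from aptatrigger.circuit import (
    GateDesignError,
    crosstalk_matrix,
    design_and_gate,
    design_not_gate,
    design_or_gate,
    predict_truth_table,
    score_activation,
    toy_gate_suite,
)
from aptatrigger.parts import generate_toy_repressor

BOOL_SPEC = {
    "OR": [False, True, True, True],
    "AND": [False, False, False, True],
    "NOT": [True, False],
}


class TestScoreActivation:
    def test_cognate_design_switches(self, start_set, toy_designs):
        for (switch, _, _), d in zip(start_set, toy_designs):
            sc = score_activation(d, switch)
            assert sc.on_score > sc.leak_score
            assert sc.on_score > 0.5
            assert sc.leak_score < 0.2

    def test_positive_control_is_ligand_independent(self, start_set):
        switch, pair, _ = start_set[0]
        sc = score_activation(pair.full_trigger, switch)
        assert sc.on_score == sc.leak_score
        assert sc.on_score > 0.5

    def test_decoy_scores_near_zero(self, start_set):
        switch = start_set[0][0]
        sc = score_activation("ACA" * 9, switch)
        assert sc.on_score < 0.05 and sc.leak_score < 0.05

    def test_on_score_monotone_in_bonus(self, start_set, toy_designs):
        switch = start_set[0][0]
        d = toy_designs[0]
        prev = 0.0
        for bonus in (0.0, -2.0, -5.0, -10.0, -20.0, -40.0):
            on = score_activation(d, switch, bonus=bonus).on_score
            assert on >= prev - 1e-12
            prev = on

    def test_dosage_raises_both_scores(self, start_set, toy_designs):
        switch = start_set[0][0]
        d = toy_designs[0]
        low = score_activation(d, switch, dosage=1.0)
        high = score_activation(d, switch, dosage=20.0)
        assert high.on_score >= low.on_score
        assert high.leak_score >= low.leak_score
        assert high.on_score > low.on_score  # strictly more drive

    def test_invalid_dosage(self, start_set, toy_designs):
        with pytest.raises(ValueError):
            score_activation(toy_designs[0], start_set[0][0], dosage=0.0)


class TestCrosstalk:
    def test_unit_diagonal_and_low_offdiagonal(self, start_set, toy_designs):
        lib = [(s, d) for (s, _, _), d in zip(start_set, toy_designs)]
        m = crosstalk_matrix(lib)
        assert (np.diag(m.values) == 1.0).all()
        assert m.max_offdiagonal() < 0.2

    def test_permutation_equivariance(self, start_set, toy_designs):
        lib = [(s, d) for (s, _, _), d in zip(start_set, toy_designs)]
        m = crosstalk_matrix(lib)
        perm = [2, 0, 3, 1]
        m_perm = crosstalk_matrix([lib[i] for i in perm])
        assert np.allclose(m_perm.values, m.values[np.ix_(perm, perm)])

    def test_all_ligands_absent_uses_leak(self, start_set, toy_designs):
        lib = [(s, d) for (s, _, _), d in zip(start_set, toy_designs)]
        state = {d.aptamer_variant.ligand: False for _, d in lib}
        m = crosstalk_matrix(lib, ligand_state=state)
        # still normalized to the (leak) diagonal
        assert (np.diag(m.values) == 1.0).all()
        raw_leak = score_activation(lib[0][1], lib[0][0]).leak_score
        raw_on = score_activation(lib[0][1], lib[0][0]).on_score
        assert raw_leak < raw_on  # the mode switch matters


class TestGates:
    @pytest.mark.parametrize("seed", range(1, 11))
    def test_truth_tables_match_boolean_spec(self, seed):
        gates = toy_gate_suite(seed)
        for kind, gate in gates.items():
            table = predict_truth_table(gate)
            assert [row.on for row in table] == BOOL_SPEC[kind], (kind, seed)

    def test_or_strands_share_trigger_domains(self):
        gate = toy_gate_suite(3)["OR"]
        seqs = [s.sequence.bases for s in gate.strands]
        assert all(s.startswith(gate.pair.b_star) for s in seqs)
        assert all(s.endswith(gate.pair.a_star) for s in seqs)

    def test_three_input_or_has_single_off_row(self, start_set):
        from aptatrigger.parts import generate_toy_aptamer, _aptamer_context_ok

        switch, pair, apt1 = start_set[0]
        extras = []
        attempt = 0
        while len(extras) < 2 and attempt < 200:
            cand = generate_toy_aptamer(
                seed=77_000_000 + attempt, stem_len=4,
                ligand=f"extra_{len(extras)}",
            )
            attempt += 1
            if _aptamer_context_ok(cand, pair):
                extras.append(cand)
        gate = design_or_gate([apt1, *extras], pair, switch)
        table = predict_truth_table(gate)
        assert len(table) == 8
        assert [row.on for row in table] == [False] + [True] * 7

    def test_duplicate_or_inputs_rejected(self, start_set):
        switch, pair, apt = start_set[0]
        with pytest.raises(ValueError, match="duplicate"):
            design_or_gate([apt, apt], pair, switch)

    def test_and_strands_carry_complementary_c_domains(self):
        from aptatrigger.sequence import reverse_complement

        gate = toy_gate_suite(3)["AND"]
        c = gate.c_domain
        assert len(c) == 8
        assert gate.strands[0].sequence.bases.endswith(c)
        assert gate.strands[1].sequence.bases.startswith(reverse_complement(c))

    def test_and_halves_do_not_activate_alone(self):
        gate = toy_gate_suite(3)["AND"]
        for strand in gate.strands:
            sc = score_activation(strand.sequence, gate.switch)
            assert sc.on_score < 0.5

    def test_not_gate_requires_repressor_switch(self, start_set, theophylline):
        activator = start_set[0][0]
        with pytest.raises(TypeError, match="repressor"):
            design_not_gate(theophylline, activator)

    def test_not_gate_rejects_composite_inputs(self, theophylline):
        rep = generate_toy_repressor(1)
        with pytest.raises(NotImplementedError, match="NOT gates take a single"):
            design_not_gate([theophylline, theophylline], rep)

    def test_threshold_limits(self):
        gate = toy_gate_suite(3)["OR"]
        assert all(r.on for r in predict_truth_table(gate, on_threshold=0.0))
        assert not any(r.on for r in predict_truth_table(gate, on_threshold=1.0))

    def test_gate_scores_strictly_inside_unit_interval(self):
        for kind, gate in toy_gate_suite(5).items():
            for row in predict_truth_table(gate):
                assert 0.0 < row.score < 1.0
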
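"""Switch activation scoring, orthogonality matrices and ligand-logic gates.

Activation is scored with a two-factor thermodynamic model:

* a *competence* factor P = exp(-penalty / rt): the Boltzmann weight of
  the trigger's binding-competent conformation (aptamer lower stem
  closed) relative to its ground state. A ligand is modelled as a
  saturating energy bonus on the closing pair, which drives the penalty
  to zero; triggers without an aptamer are always competent.
* a *drive* factor sigma(-(dG_duplex - dG_switch + offset - rt ln d)/s):
  a logistic in the net free energy gained by unwinding the switch
  hairpin and forming the trigger:switch duplex. ``offset`` is the
  minimum net drive required for strand displacement to proceed
  (association entropy plus invasion barrier, lumped); ``d`` is a trigger
  dosage multiplier entering as a chemical-potential shift.

on_score uses the saturating bonus, leak_score uses bonus 0; both lie in
(0, 1). The score is an ordering device, not a fluorescence predictor;
only orderings are asserted anywhere.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass

import numpy as np

from . import thermo
from .design import AptaTriggerDesign, assemble_apta_trigger
from .params import default_parameters
from .parts import AptamerSpec, PartialTriggerPair, SwitchSpec
from .sequence import NucleicSequence, SequenceError, as_sequence, reverse_complement

__all__ = [
    "ActivationScore",
    "CrosstalkMatrix",
    "LogicGateDesign",
    "GateStrand",
    "TruthTableRow",
    "score_activation",
    "predict_leak",
    "crosstalk_matrix",
    "design_or_gate",
    "design_and_gate",
    "design_not_gate",
    "predict_truth_table",
]

RT = default_parameters().rt

#: ligand modelled as a saturating stabilization of the competent state
SATURATING_BONUS = -20.0

#: logistic scale (kcal/mol) mapping net drive to a score in (0, 1)
DEFAULT_SCALE = 4.0

#: minimum net thermodynamic drive (kcal/mol) for strand displacement
ACTIVATION_OFFSET = 8.0

#: toehold-access gating: displacement must nucleate at the free toehold
TOEHOLD_OFFSET = 7.0
TOEHOLD_SCALE = 1.5


@dataclass(frozen=True)
class ActivationScore:
    """Predicted switch activation with (on) and without (leak) ligand."""

    on_score: float
    leak_score: float

    def __post_init__(self) -> None:
        for label, v in (("on_score", self.on_score), ("leak_score", self.leak_score)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {v}")


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _competence(seq: NucleicSequence, span: tuple[int, int] | None,
                bonus: float, params) -> float:
    """Boltzmann weight of the competent (stem-closed) conformation."""
    if span is None:
        return 1.0
    mfe = thermo.fold_mfe(seq, params)
    closed = thermo.fold_constrained_pair(seq, span[0], span[1] - 1, params)
    if closed is None:
        return 0.0
    penalty = max(0.0, closed.dg + bonus - mfe.dg)
    return math.exp(-penalty / RT)


def _drive_score(trigger: NucleicSequence, switch: SwitchSpec, dosage: float,
                 scale: float, params) -> float:
    """Net displacement drive, gated by toehold accessibility.

    Strand displacement nucleates at the single-stranded toehold, so the
    overall drive is the product of a logistic in the trigger:toehold
    hybridization energy and a logistic in the net reaction free energy
    (duplex formed, switch hairpin unwound).
    """
    g_toe, _ = thermo.duplex_mfe(trigger.bases, switch.toehold, params)
    toe_access = _logistic(-(g_toe + TOEHOLD_OFFSET) / TOEHOLD_SCALE)
    g_sw = thermo.fold_mfe(switch.sequence, params).dg
    g_dup, _ = thermo.duplex_mfe(trigger.bases, switch.sequence.bases, params)
    dg_eff = g_dup - g_sw + ACTIVATION_OFFSET - RT * math.log(dosage)
    return toe_access * _logistic(-dg_eff / scale)


def _trigger_parts(
    design,
) -> tuple[NucleicSequence, NucleicSequence, tuple[int, int] | None]:
    """(full strand, presented displacement domains, aptamer span).

    In the binding-competent conformation the aptamer folds compactly and
    presents b* and a* in proximity, so the displacement drive is scored
    on the joined domains; the competence factor is scored on the full
    strand. A plain sequence is its own presented domain set.
    """
    if isinstance(design, AptaTriggerDesign):
        presented = NucleicSequence(
            f"{design.name}_domains", design.b_star + design.a_star
        )
        return design.full_sequence, presented, design.aptamer_span
    seq = as_sequence(design, "trigger")
    return seq, seq, None


def score_activation(
    design: "AptaTriggerDesign | NucleicSequence | str",
    switch: SwitchSpec,
    dosage: float = 1.0,
    bonus: float = SATURATING_BONUS,
    scale: float = DEFAULT_SCALE,
    params=None,
) -> ActivationScore:
    """Predicted activation of a switch by a trigger, with/without ligand.

    Plain sequences (e.g. a positive-control full trigger) carry no
    aptamer and score identically with and without ligand.
    """
    if dosage <= 0:
        raise ValueError("dosage must be positive")
    params = params or default_parameters()
    strand, presented, span = _trigger_parts(design)
    drive = _drive_score(presented, switch, dosage, scale, params)
    p_on = _competence(strand, span, bonus, params)
    p_leak = _competence(strand, span, 0.0, params)
    return ActivationScore(on_score=p_on * drive, leak_score=p_leak * drive)


def predict_leak(design, switch: SwitchSpec, **kwargs) -> float:
    """Predicted ligand-free (spontaneous) activation of the switch."""
    return score_activation(design, switch, **kwargs).leak_score


# --- orthogonality --------------------------------------------------------


@dataclass(frozen=True)
class CrosstalkMatrix:
    """Relative activation for every trigger x switch pair.

    Each column is normalized by its cognate (diagonal) entry, so the
    diagonal is exactly 1 and off-diagonal entries measure crosstalk.
    """

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("crosstalk matrix shape mismatch")
        if (self.values < 0).any():
            raise ValueError("crosstalk entries must be >= 0")

    def max_offdiagonal(self) -> float:
        mask = ~np.eye(len(self.rows), dtype=bool)
        return float(self.values[mask].max())


def crosstalk_matrix(
    library: "list[tuple[SwitchSpec, AptaTriggerDesign]]",
    ligand_state: "dict[str, bool] | None" = None,
    dosage: float = 1.0,
    params=None,
) -> CrosstalkMatrix:
    """Cognate-normalized activation matrix over a switch/trigger library.

    ``ligand_state`` maps ligand names to presence; missing ligands
    default to present. With every ligand absent, entries are computed
    from leak scores instead of ligand-saturated scores.
    """
    ligand_state = ligand_state or {}
    n = len(library)
    raw = np.zeros((n, n))
    for i, (_, design) in enumerate(library):
        ligand = design.aptamer_variant.ligand
        present = ligand_state.get(ligand, True)
        for j, (switch, _) in enumerate(library):
            score = score_activation(design, switch, dosage=dosage, params=params)
            raw[i, j] = score.on_score if present else score.leak_score
    values = np.zeros_like(raw)
    for j in range(n):
        cognate = raw[j, j]
        if cognate <= 0:
            pair = library[j]
            raise ZeroDivisionError(
                f"cognate activation is zero for switch {pair[0].name!r} / "
                f"trigger {pair[1].name!r}; cannot normalize"
            )
        values[:, j] = raw[:, j] / cognate
    return CrosstalkMatrix(
        rows=tuple(d.name for _, d in library),
        cols=tuple(s.name for s, _ in library),
        values=values,
    )


# --- logic gates ----------------------------------------------------------


@dataclass(frozen=True)
class GateStrand:
    """One RNA strand of a logic gate with its aptamer annotation."""

    label: str
    sequence: NucleicSequence
    aptamer_span: tuple[int, int] | None
    ligand: str | None


@dataclass(frozen=True)
class LogicGateDesign:
    """An OR/AND/NOT ligand-logic gate over one switch."""

    gate_type: str
    switch: SwitchSpec
    strands: tuple[GateStrand, ...]
    ligand_inputs: tuple[str, ...]
    pair: PartialTriggerPair
    c_domain: str | None = None

    def __post_init__(self) -> None:
        if self.gate_type not in ("OR", "AND", "NOT"):
            raise ValueError(f"unknown gate type {self.gate_type!r}")

    @property
    def components(self) -> list[dict]:
        """Annotated component listing (for JSON/FASTA export)."""
        out = [{"role": "switch", "name": self.switch.name,
                "sequence": self.switch.sequence.bases}]
        for s in self.strands:
            out.append({
                "role": "trigger_strand",
                "name": s.label,
                "sequence": s.sequence.bases,
                "aptamer_span": list(s.aptamer_span) if s.aptamer_span else None,
                "ligand": s.ligand,
            })
        return out


def _design_strand(design: AptaTriggerDesign) -> GateStrand:
    return GateStrand(
        label=design.name,
        sequence=design.full_sequence,
        aptamer_span=design.aptamer_span,
        ligand=design.aptamer_variant.ligand,
    )


def design_or_gate(
    aptamers: "list[AptamerSpec]",
    pair: PartialTriggerPair,
    switch: SwitchSpec,
    linker_len: int = 3,
) -> LogicGateDesign:
    """OR gate: one apta-trigger per ligand, sharing identical a*/b* domains.

    Any single ligand stabilizes its trigger, and any stabilized trigger
    can activate the shared switch.
    """
    if len(aptamers) < 2:
        raise ValueError("an OR gate needs at least 2 aptamers")
    ligands = [a.ligand for a in aptamers]
    if len(set(ligands)) != len(ligands):
        raise ValueError(f"duplicate ligand inputs in OR gate: {ligands}")
    strands = []
    for version, apt in enumerate(aptamers, start=1):
        d = assemble_apta_trigger(
            pair, apt, linker_len=linker_len, switch_id="B", version=version
        )
        strands.append(_design_strand(d))
    return LogicGateDesign(
        gate_type="OR", switch=switch, strands=tuple(strands),
        ligand_inputs=tuple(ligands), pair=pair,
    )


class GateDesignError(RuntimeError):
    """A gate design constraint could not be satisfied."""


def _pick_c_domain(pair: PartialTriggerPair, switch: SwitchSpec, c_len: int,
                   cross_threshold: float, params) -> str:
    """Deterministic search for a c/c* assembly domain.

    The domain (and its complement) must not cross-react with the switch:
    both duplex energies must stay above ``cross_threshold``.
    """
    seed = zlib.crc32((pair.full_trigger + switch.sequence.bases).encode())
    rng = np.random.default_rng(seed % 2**31)
    diagnostics = []
    for _ in range(200):
        c = "".join(rng.choice(list("ACGU"), size=c_len, p=[0.3, 0.25, 0.25, 0.2]))
        gc = sum(1 for b in c if b in "GC")
        if not c_len // 3 <= gc <= 2 * c_len // 3 + 1:
            continue
        e1, _ = thermo.duplex_mfe(c, switch.sequence.bases, params)
        e2, _ = thermo.duplex_mfe(reverse_complement(c), switch.sequence.bases, params)
        if e1 > cross_threshold and e2 > cross_threshold:
            return c
        diagnostics.append((c, e1, e2))
    raise GateDesignError(
        f"no c domain of length {c_len} clears the cross-reactivity threshold "
        f"{cross_threshold} kcal/mol vs switch {switch.name!r}; "
        f"last candidates: {diagnostics[-3:]}"
    )


def design_and_gate(
    apt1: AptamerSpec,
    apt2: AptamerSpec,
    pair: PartialTriggerPair,
    switch: SwitchSpec,
    c_len: int = 8,
    cross_threshold: float = -8.0,
    linker_len: int = 3,
    params=None,
) -> LogicGateDesign:
    """AND gate: the trigger is split across two aptamer-gated strands.

    Strand 1 carries b* | aptamer 1 | c, strand 2 carries c* | aptamer 2 |
    a*; the c/c* domain assembles the complex, and both ligands are
    required to present b* and a* in proximity.
    """
    if c_len < 6:
        raise ValueError("c_len must be >= 6")
    if apt1.ligand == apt2.ligand:
        raise ValueError("AND gate inputs must sense different ligands")
    params = params or default_parameters()
    c = _pick_c_domain(pair, switch, c_len, cross_threshold, params)
    linker = "A" * linker_len
    s1_bases = pair.b_star + linker + apt1.sequence.bases + linker + c
    s2_bases = reverse_complement(c) + linker + apt2.sequence.bases + linker + pair.a_star
    for label, bases in (("strand 1", s1_bases), ("strand 2", s2_bases)):
        if pair.a_star in bases and pair.b_star in bases:
            raise GateDesignError(f"{label} contains both a* and b*")
    span1_start = len(pair.b_star) + linker_len
    span2_start = c_len + linker_len
    strands = (
        GateStrand("and_strand1", NucleicSequence("and_strand1", s1_bases),
                   (span1_start, span1_start + len(apt1.sequence)), apt1.ligand),
        GateStrand("and_strand2", NucleicSequence("and_strand2", s2_bases),
                   (span2_start, span2_start + len(apt2.sequence)), apt2.ligand),
    )
    # neither half may activate the switch on its own
    for strand in strands:
        half_drive = _drive_score(strand.sequence, switch, 1.0, DEFAULT_SCALE, params)
        if half_drive >= 0.35:
            raise GateDesignError(
                f"{strand.label} alone drives switch {switch.name!r} "
                f"(drive score {half_drive:.2f}); the half would leak - choose "
                "a different aptamer or partial triggers"
            )
        _require_structure_switching(strand, params)
    return LogicGateDesign(
        gate_type="AND", switch=switch, strands=strands,
        ligand_inputs=(apt1.ligand, apt2.ligand), pair=pair, c_domain=c,
    )


def design_not_gate(
    apt: AptamerSpec,
    repressor_switch: SwitchSpec,
    linker_len: int = 3,
) -> LogicGateDesign:
    """NOT gate: an apta-trigger against a three-way-junction repressor.

    The repressor switch translates by default; a ligand-stabilized
    trigger forms the repressing three-way-junction complex, so output is
    ON without ligand and OFF with it. Composite inputs (e.g. feeding OR
    outputs into NOT for a NOR) are out of scope and rejected.
    """
    if isinstance(apt, (list, tuple, LogicGateDesign)):
        raise NotImplementedError(
            "NOT gates take a single aptamer input; composing NOT with other "
            "gates (NOR/NAND) is not supported"
        )
    if repressor_switch.switch_type != "repressor":
        raise TypeError(
            f"switch {repressor_switch.name!r} is an activator-type switch; "
            "a NOT gate needs a repressor-type (3WJ) switch"
        )
    pair = repressor_switch.cognate_pair()
    d = assemble_apta_trigger(pair, apt, linker_len=linker_len, switch_id="R", version=1)
    strand = _design_strand(d)
    _require_structure_switching(strand, default_parameters())
    return LogicGateDesign(
        gate_type="NOT", switch=repressor_switch, strands=(strand,),
        ligand_inputs=(apt.ligand,), pair=pair,
    )


#: a gate strand must pay at least this much (kcal/mol) to close its stem
#: without ligand, or it is constitutively competent and cannot gate
MIN_SWITCHING_PENALTY = 0.5


def _require_structure_switching(strand: GateStrand, params) -> None:
    p_leak = _competence(strand.sequence, strand.aptamer_span, 0.0, params)
    limit = math.exp(-MIN_SWITCHING_PENALTY / RT)
    if p_leak > limit:
        raise GateDesignError(
            f"{strand.label}: the aptamer's competent conformation is (nearly) "
            f"the ground state in this strand context (leak competence "
            f"{p_leak:.2f}); the strand cannot act as a ligand gate"
        )


@dataclass(frozen=True)
class TruthTableRow:
    inputs: tuple[bool, ...]
    score: float
    on: bool


def toy_gate_suite(seed: int, stem_len: int = 4) -> dict[str, LogicGateDesign]:
    """One seeded OR, AND and NOT gate instance over toy parts.

    Builds a toy switch with a matched aptamer, then searches a derived
    seed stream for a second aptamer whose AND-gate halves pass the
    single-strand leak rejection. Deterministic for a fixed seed.
    """
    from .parts import (
        GenerationError,
        _aptamer_context_ok,
        generate_toy_aptamer,
        generate_toy_repressor,
        generate_toy_start_set,
    )

    (switch, pair, apt1), = generate_toy_start_set(1, seed, stem_len=stem_len)
    and_gate = None
    apt2 = None
    for attempt in range(120):
        candidate = generate_toy_aptamer(
            seed=900_000_000 + seed * 1000 + attempt,
            stem_len=stem_len,
            ligand="ligand_Z",
        )
        if not _aptamer_context_ok(candidate, pair):
            continue
        try:
            and_gate = design_and_gate(apt1, candidate, pair, switch)
        except GateDesignError:
            continue
        apt2 = candidate
        break
    if and_gate is None or apt2 is None:
        raise GenerationError(f"no AND-compatible second aptamer for seed {seed}")

    repressor = generate_toy_repressor(seed)
    not_gate = None
    for attempt in range(120):
        if attempt == 0:
            candidate = apt1
        else:
            candidate = generate_toy_aptamer(
                seed=910_000_000 + seed * 1000 + attempt,
                stem_len=stem_len,
                ligand=apt1.ligand,
            )
            if not _aptamer_context_ok(candidate, repressor.cognate_pair()):
                continue
        try:
            not_gate = design_not_gate(candidate, repressor)
            break
        except GateDesignError:
            continue
    if not_gate is None:
        raise GenerationError(f"no NOT-compatible aptamer for seed {seed}")
    return {
        "OR": design_or_gate([apt1, apt2], pair, switch),
        "AND": and_gate,
        "NOT": not_gate,
    }


def _strand_competence(strand: GateStrand, present: bool, params) -> float:
    bonus = SATURATING_BONUS if present else 0.0
    return _competence(strand.sequence, strand.aptamer_span, bonus, params)


def _gate_score(gate: LogicGateDesign, state: "dict[str, bool]",
                dosage: float, scale: float, params) -> float:
    full = NucleicSequence("presented_domains", gate.pair.full_trigger)
    if gate.gate_type == "OR":
        drive = _drive_score(full, gate.switch, dosage, scale, params)
        best = 0.0
        for strand in gate.strands:
            p = _strand_competence(strand, state[strand.ligand], params)
            best = max(best, p * drive)
        return best
    if gate.gate_type == "AND":
        p = 1.0
        for strand in gate.strands:
            p *= _strand_competence(strand, state[strand.ligand], params)
        c = gate.c_domain or ""
        e_cc, _ = thermo.duplex_mfe(c, reverse_complement(c), params)
        assembly = _logistic(-(e_cc + 4.0) / scale)
        drive = _drive_score(full, gate.switch, dosage, scale, params)
        return p * assembly * drive
    # NOT: output = 1 - repression
    strand = gate.strands[0]
    p = _strand_competence(strand, state[strand.ligand], params)
    drive = _drive_score(full, gate.switch, dosage, scale, params)
    return 1.0 - p * drive


def predict_truth_table(
    gate: LogicGateDesign,
    on_threshold: float = 0.5,
    dosage: float = 1.0,
    scale: float = DEFAULT_SCALE,
    params=None,
) -> list[TruthTableRow]:
    """Evaluate a gate over all 2^k ligand combinations.

    Ligand presence applies the saturating aptamer bonus to the matching
    strand; a row is ON when its score strictly exceeds ``on_threshold``
    (scores are strictly inside (0, 1), so threshold 0 turns every row ON
    and threshold 1 every row OFF).
    """
    params = params or default_parameters()
    rows = []
    for combo in itertools.product((False, True), repeat=len(gate.ligand_inputs)):
        state = dict(zip(gate.ligand_inputs, combo))
        score = _gate_score(gate, state, dosage, scale, params)
        rows.append(TruthTableRow(inputs=combo, score=score, on=score > on_threshold))
    return rows
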
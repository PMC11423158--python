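"""Typed registry of biological parts: aptamers, toehold switches, triggers.

Packaged parts cover the three literature aptamers used throughout the
toolkit (theophylline, tetracycline, MS2 coat-protein hairpin); seeded
generators produce orthogonal toy switch libraries and toy structure-
switching aptamers so that every downstream module is fully testable
offline.

Part files are JSON with 0-based, half-open domain coordinates. Kd values
default to literature placeholders and are flagged as such: the
dose-response machinery treats them as user configuration.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .sequence import (
    NucleicSequence,
    SequenceError,
    can_pair,
    normalize_bases,
    reverse_complement,
)
from . import thermo

__all__ = [
    "AptamerSpec",
    "SwitchSpec",
    "PartialTriggerPair",
    "PartLookupError",
    "GenerationError",
    "load_aptamer",
    "list_aptamers",
    "read_part_file",
    "write_part_file",
    "generate_toy_switch_library",
    "generate_toy_aptamer",
    "generate_toy_repressor",
    "generate_toy_start_set",
    "stem_closure_energy",
]

MAX_STEM_LEN = 8


class PartLookupError(KeyError):
    """Unknown part name."""


class GenerationError(RuntimeError):
    """Fixture generation failed to satisfy its constraints."""


def _check_arms(stem5: str, stem3: str, context: str,
                max_len: int | None = None) -> None:
    if len(stem5) != len(stem3):
        raise SequenceError(f"{context}: stem arms differ in length")
    if max_len is not None and len(stem5) > max_len:
        raise SequenceError(f"{context}: stem arms longer than {max_len}")
    for k in range(len(stem5)):
        x, y = stem5[k], stem3[len(stem3) - 1 - k]
        if not can_pair(x, y):
            raise SequenceError(
                f"{context}: stem arms not complementary at arm position {k} "
                f"({x} vs {y}; allowed pairs are AU/UA/CG/GC/GU/UG)"
            )


@dataclass(frozen=True)
class AptamerSpec:
    """An aptamer core with an engineerable lower stem.

    The core is the ligand-contacting region and is treated as immutable;
    only the lower-stem arms (``stem5``/``stem3``, 0-8 nt, validated as
    reverse-complementary under canonical pairing) are modified by the
    design machinery. ``kd`` is the ligand dissociation constant in molar;
    packaged values are literature placeholders (``kd_is_placeholder``).
    """

    name: str
    ligand: str
    core: NucleicSequence
    stem5: str
    stem3: str
    kd: float | None = None
    kd_is_placeholder: bool = False
    stem5_variants: tuple[str, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stem5", normalize_bases(self.stem5) if self.stem5 else "")
        object.__setattr__(self, "stem3", normalize_bases(self.stem3) if self.stem3 else "")
        if len(self.core) < 1:
            raise SequenceError(f"aptamer {self.name!r}: core must be non-empty")
        _check_arms(self.stem5, self.stem3, f"aptamer {self.name!r}",
                    max_len=MAX_STEM_LEN)
        if self.kd is not None and self.kd <= 0:
            raise SequenceError(f"aptamer {self.name!r}: kd must be positive")

    @property
    def sequence(self) -> NucleicSequence:
        """Full aptamer: stem5 + core + stem3."""
        return NucleicSequence(self.name, self.stem5 + self.core.bases + self.stem3)

    @property
    def stem_len(self) -> int:
        return len(self.stem5)

    def with_stem(self, stem5: str, stem3: str | None = None,
                  name: str | None = None) -> "AptamerSpec":
        """A stem-arm variant sharing this aptamer's core.

        If ``stem3`` is omitted it is the strict reverse complement of
        ``stem5``.
        """
        stem5 = normalize_bases(stem5) if stem5 else ""
        if stem3 is None:
            stem3 = reverse_complement(stem5)
        return replace(self, stem5=stem5, stem3=stem3,
                       name=name or f"{self.name}_{stem5 or 'stemless'}")


@dataclass(frozen=True)
class SwitchSpec:
    """A toehold switch: hairpin sequestering the start codon, free toehold.

    Layout 5'->3': toehold | stem_bottom | loop (contains the RBS) |
    stem_top (ends with the AUG start codon). The cognate trigger is the
    reverse complement of toehold + stem_bottom. ``switch_type`` is
    "activator" (translation ON upon trigger binding) or "repressor"
    (three-way-junction repressor: trigger binding turns translation OFF).
    """

    name: str
    toehold: str
    stem_bottom: str
    loop: str
    stem_top: str
    start_codon: int
    reporter_label: str = "gfp"
    switch_type: str = "activator"

    def __post_init__(self) -> None:
        for attr in ("toehold", "stem_bottom", "loop", "stem_top"):
            object.__setattr__(self, attr, normalize_bases(getattr(self, attr)))
        if self.switch_type not in ("activator", "repressor"):
            raise SequenceError(f"switch {self.name!r}: unknown type {self.switch_type!r}")
        _check_arms(self.stem_bottom, self.stem_top, f"switch {self.name!r}")
        if "AGGAGG" not in self.loop:
            raise SequenceError(f"switch {self.name!r}: loop must contain the RBS (AGGAGG)")
        seq = self.sequence.bases
        if seq[self.start_codon:self.start_codon + 3] != "AUG":
            raise SequenceError(
                f"switch {self.name!r}: no AUG at start_codon index {self.start_codon}"
            )
        stem_loop_start = len(self.toehold)
        if not stem_loop_start <= self.start_codon < len(seq):
            raise SequenceError(
                f"switch {self.name!r}: start codon must lie in the stem/loop region"
            )

    @property
    def sequence(self) -> NucleicSequence:
        return NucleicSequence(
            self.name, self.toehold + self.stem_bottom + self.loop + self.stem_top
        )

    @property
    def recognition_length(self) -> int:
        """Length of the trigger-binding region (toehold + stem_bottom)."""
        return len(self.toehold) + len(self.stem_bottom)

    def cognate_pair(self) -> "PartialTriggerPair":
        """The cognate partial-trigger pair (b* | a*) for this switch."""
        return PartialTriggerPair(
            a_star=reverse_complement(self.toehold),
            b_star=reverse_complement(self.stem_bottom),
        )

    def toehold_unpaired_in_mfe(self) -> bool:
        db = thermo.fold_mfe(self.sequence).structure.db
        return set(db[: len(self.toehold)]) <= {"."}


@dataclass(frozen=True)
class PartialTriggerPair:
    """The two halves of a split trigger: b* (displacement) and a* (toehold).

    Concatenated 5'-b*-a*-3' they form the full cognate trigger of a
    switch; each domain must be at least 6 nt.
    """

    a_star: str
    b_star: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_star", normalize_bases(self.a_star))
        object.__setattr__(self, "b_star", normalize_bases(self.b_star))
        for label, dom in (("a*", self.a_star), ("b*", self.b_star)):
            if len(dom) < 6:
                raise SequenceError(f"partial trigger domain {label} shorter than 6 nt")

    @property
    def full_trigger(self) -> str:
        return self.b_star + self.a_star


# --- packaged parts -------------------------------------------------------


def _parts_dir():
    return importlib.resources.files("aptatrigger") / "data" / "parts"


def list_aptamers() -> list[str]:
    """Names of all packaged aptamer parts."""
    return sorted(p.name[: -len(".json")] for p in _parts_dir().iterdir()
                  if p.name.endswith(".json"))


def load_aptamer(name: str | Path) -> AptamerSpec:
    """Load a packaged aptamer by name, or any part file by path."""
    candidate = Path(str(name))
    if candidate.suffix == ".json" and candidate.exists():
        part = read_part_file(candidate)
    else:
        ref = _parts_dir() / f"{name}.json"
        if not ref.is_file():
            raise PartLookupError(
                f"unknown aptamer {name!r}; available parts: {', '.join(list_aptamers())}"
            )
        part = _part_from_dict(json.loads(ref.read_text()))
    if not isinstance(part, AptamerSpec):
        raise PartLookupError(f"part {name!r} is not an aptamer")
    return part


def _part_to_dict(part: "AptamerSpec | SwitchSpec") -> dict:
    if isinstance(part, AptamerSpec):
        ns, nc = len(part.stem5), len(part.core)
        return {
            "part_type": "aptamer",
            "name": part.name,
            "ligand": part.ligand,
            "core": part.core.bases,
            "stem5": part.stem5,
            "stem3": part.stem3,
            "kd_molar": part.kd,
            "kd_is_placeholder": part.kd_is_placeholder,
            "stem5_variants": list(part.stem5_variants),
            "provenance": part.provenance,
            "domains": {
                "stem5": [0, ns],
                "core": [ns, ns + nc],
                "stem3": [ns + nc, ns + nc + len(part.stem3)],
            },
        }
    if isinstance(part, SwitchSpec):
        lt, lb, ll = len(part.toehold), len(part.stem_bottom), len(part.loop)
        return {
            "part_type": "switch",
            "name": part.name,
            "toehold": part.toehold,
            "stem_bottom": part.stem_bottom,
            "loop": part.loop,
            "stem_top": part.stem_top,
            "start_codon": part.start_codon,
            "reporter_label": part.reporter_label,
            "switch_type": part.switch_type,
            "domains": {
                "toehold": [0, lt],
                "stem_bottom": [lt, lt + lb],
                "loop": [lt + lb, lt + lb + ll],
                "stem_top": [lt + lb + ll, lt + lb + ll + len(part.stem_top)],
            },
        }
    raise TypeError(f"unsupported part type {type(part).__name__}")


def _part_from_dict(data: dict) -> "AptamerSpec | SwitchSpec":
    kind = data.get("part_type")
    if kind == "aptamer":
        return AptamerSpec(
            name=data["name"],
            ligand=data["ligand"],
            core=NucleicSequence(data["name"] + "_core", data["core"]),
            stem5=data["stem5"],
            stem3=data["stem3"],
            kd=data.get("kd_molar"),
            kd_is_placeholder=bool(data.get("kd_is_placeholder", False)),
            stem5_variants=tuple(data.get("stem5_variants", ())),
            provenance=data.get("provenance", ""),
        )
    if kind == "switch":
        return SwitchSpec(
            name=data["name"],
            toehold=data["toehold"],
            stem_bottom=data["stem_bottom"],
            loop=data["loop"],
            stem_top=data["stem_top"],
            start_codon=data["start_codon"],
            reporter_label=data.get("reporter_label", "gfp"),
            switch_type=data.get("switch_type", "activator"),
        )
    raise SequenceError(f"unknown part_type {kind!r} in part file")


def write_part_file(part: "AptamerSpec | SwitchSpec", path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_part_to_dict(part), indent=2, sort_keys=True) + "\n"
    )


def read_part_file(path: str | Path) -> "AptamerSpec | SwitchSpec":
    return _part_from_dict(json.loads(Path(path).read_text()))


# --- seeded fixture generators -------------------------------------------

_LOOP = "AAAGGAGGAUAA"  # 12 nt, RBS at positions 3-8


def _draw(rng: np.random.Generator, k: int, bases: str, weights) -> str:
    return "".join(rng.choice(list(bases), size=k, p=weights))


def _propose_switch(rng: np.random.Generator, idx: int) -> SwitchSpec | None:
    """One random toy switch candidate (hairpin-forming, free toehold)."""
    toehold = _draw(rng, 12, "AUCG", [0.36, 0.36, 0.2, 0.08])
    stem_bottom = "CAU" + _draw(rng, 9, "GCAU", [0.3, 0.3, 0.2, 0.2])
    stem_top = reverse_complement(stem_bottom)
    seq_len = len(toehold) + len(stem_bottom) + len(_LOOP) + len(stem_top)
    try:
        switch = SwitchSpec(
            name=f"toy_{chr(65 + idx)}",
            toehold=toehold,
            stem_bottom=stem_bottom,
            loop=_LOOP,
            stem_top=stem_top,
            start_codon=seq_len - 3,
        )
    except SequenceError:
        return None
    if not switch.toehold_unpaired_in_mfe():
        return None
    db = thermo.fold_mfe(switch.sequence).structure.db
    stem_start = len(switch.toehold)
    n_paired = sum(1 for c in db[stem_start:stem_start + 12] if c == "(")
    if n_paired < 10:
        return None
    return switch


def _switch_orthogonal(
    switch: SwitchSpec,
    pair: PartialTriggerPair,
    accepted: list,
    ortho_threshold: float,
    activation_threshold: float,
) -> bool:
    e_cog, _ = thermo.duplex_mfe(pair.full_trigger, switch.sequence.bases)
    if e_cog > activation_threshold:
        return False
    # net displacement drive: duplex gain must clearly beat the hairpin
    g_sw = thermo.fold_mfe(switch.sequence).dg
    if e_cog - g_sw > -12.0:
        return False
    # the toehold itself must nucleate trigger binding strongly
    e_toe, _ = thermo.duplex_mfe(pair.full_trigger, switch.toehold)
    if e_toe > -9.0:
        return False
    for entry in accepted:
        other_switch, other_pair = entry[0], entry[1]
        e1, _ = thermo.duplex_mfe(pair.full_trigger, other_switch.sequence.bases)
        e2, _ = thermo.duplex_mfe(other_pair.full_trigger, switch.sequence.bases)
        if e1 <= ortho_threshold or e2 <= ortho_threshold:
            return False
    return True


def generate_toy_switch_library(
    n: int,
    seed: int,
    ortho_threshold: float = -8.0,
    activation_threshold: float = -25.0,
    max_retries_per_switch: int = 200,
) -> list[tuple[SwitchSpec, PartialTriggerPair]]:
    """A seeded library of mutually orthogonal toy toehold switches.

    Each switch folds into a hairpin sequestering its start codon with the
    toehold single-stranded; every cognate trigger:switch duplex is
    stronger (more negative) than ``activation_threshold`` while every
    non-cognate trigger:switch duplex is weaker than ``ortho_threshold``.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[tuple[SwitchSpec, PartialTriggerPair]] = []
    for idx in range(n):
        for _attempt in range(max_retries_per_switch):
            switch = _propose_switch(rng, idx)
            if switch is None:
                continue
            pair = switch.cognate_pair()
            if _switch_orthogonal(switch, pair, accepted,
                                  ortho_threshold, activation_threshold):
                accepted.append((switch, pair))
                break
        else:
            raise GenerationError(
                f"could not generate switch {idx + 1}/{n} after "
                f"{max_retries_per_switch} attempts; try a smaller n or another seed"
            )
    return accepted


def generate_toy_aptamer(
    seed: int,
    stem_len: int = 4,
    ligand: str | None = None,
    penalty_range: tuple[float, float] = (0.5, 9.0),
    max_retries: int = 500,
) -> AptamerSpec:
    """A seeded synthetic structure-switching aptamer.

    The lower stem (3-5 nt, mainly weak A-U pairs closed through one
    wobble G:U) competes with a decoy segment inside the core that pairs
    the 5' arm through a stronger Watson-Crick G:C. The non-binding
    (decoy-paired) conformation is therefore the ground state, and closing
    the lower stem costs a penalty within ``penalty_range`` kcal/mol -
    exactly the structure-switching margin a ligand bonus can pay.
    """
    if not 3 <= stem_len <= 5:
        raise ValueError("stem_len must be in 3..5")
    rng = np.random.default_rng(seed)
    for _attempt in range(max_retries):
        arm = list(_draw(rng, stem_len, "AU", [0.5, 0.5]))
        arm[int(rng.integers(0, stem_len))] = "G"
        stem5 = "".join(arm)
        stem3 = reverse_complement(stem5, wobble=True)
        decoy = reverse_complement(stem5)
        s1 = _draw(rng, 4, "AC", [0.6, 0.4])
        s2 = _draw(rng, 5, "AC", [0.6, 0.4])
        core = s1 + decoy + s2
        apt = AptamerSpec(
            name=f"toy_apt_s{seed}_l{stem_len}",
            ligand=ligand or f"toyligand_{seed}",
            core=NucleicSequence(f"toy_apt_s{seed}_core", core),
            stem5=stem5,
            stem3=stem3,
            kd=1e-6,
            kd_is_placeholder=True,
            provenance=f"synthetic toy aptamer, seed={seed}, stem_len={stem_len}",
        )
        if _structure_switching_ok(apt.sequence.bases, penalty_range):
            return apt
    raise GenerationError(
        f"no structure-switching aptamer found for seed={seed}, stem_len={stem_len}"
    )


def _closure_penalty(apt_bases: str, flank5: str = "AAA",
                     flank3: str = "AAA") -> float | None:
    """Cost (kcal/mol) of closing the lower stem in a flanked context.

    None if the closing pair cannot form, 0 if the closed conformation is
    already the ground state.
    """
    probe = flank5 + apt_bases + flank3
    i = len(flank5)
    j = len(probe) - len(flank3) - 1
    mfe = thermo.fold_mfe(probe)
    closed = thermo.fold_constrained_pair(probe, i, j)
    if closed is None:
        return None
    return closed.dg - mfe.dg


def _structure_switching_ok(apt_bases: str, penalty_range: tuple[float, float],
                            flank5: str = "AAA", flank3: str = "AAA") -> bool:
    """True if the closed lower stem is a strict excited state of the probe."""
    pen = _closure_penalty(apt_bases, flank5, flank3)
    if pen is None:
        return False
    lo, hi = penalty_range
    return lo <= pen <= hi


def generate_toy_repressor(seed: int, max_retries: int = 200) -> SwitchSpec:
    """A toy three-way-junction repressor switch.

    Translation is ON by default (only a weak A/U hairpin, accessible
    RBS); a bound trigger forms a stable switch:trigger complex that
    represses. Shares the trigger geometry of the activator switches, and
    the same acceptance margins: the cognate trigger must out-compete the
    residual hairpin by >= 12 kcal/mol and bind the toehold below
    -9 kcal/mol, so repression is decisive.
    """
    rng = np.random.default_rng(seed)
    for _attempt in range(max_retries):
        toehold = _draw(rng, 12, "AUCG", [0.36, 0.36, 0.2, 0.08])
        stem_bottom = "CAU" + _draw(rng, 9, "AU", [0.5, 0.5])
        stem_top = reverse_complement(stem_bottom)
        seq_len = len(toehold) + len(stem_bottom) + len(_LOOP) + len(stem_top)
        switch = SwitchSpec(
            name=f"toy_rep_{seed}",
            toehold=toehold,
            stem_bottom=stem_bottom,
            loop=_LOOP,
            stem_top=stem_top,
            start_codon=seq_len - 3,
            switch_type="repressor",
        )
        pair = switch.cognate_pair()
        e_cog, _ = thermo.duplex_mfe(pair.full_trigger, switch.sequence.bases)
        g_sw = thermo.fold_mfe(switch.sequence).dg
        if e_cog - g_sw > -12.0:
            continue
        e_toe, _ = thermo.duplex_mfe(pair.full_trigger, switch.toehold)
        if e_toe > -9.0:
            continue
        return switch
    raise GenerationError(
        f"could not generate a repressor switch for seed {seed}"
    )


def generate_toy_start_set(
    n: int,
    seed: int,
    stem_len: int = 4,
) -> list[tuple[SwitchSpec, PartialTriggerPair, AptamerSpec]]:
    """Matched toy switches, trigger pairs and aptamers for circuit tests.

    Each aptamer is re-checked inside its assembled trigger context
    (b* | AAA | aptamer | AAA | a*): the structure-switching penalty must
    survive the flanking trigger domains and stay context-invariant
    (within 0.02 kcal/mol of the minimal-flank value, also under trimmed
    domains), i.e. the trigger tails do not fold onto the aptamer. This
    makes leak predictions monotone under partial-trigger trimming.
    Switches and aptamers are co-selected: a switch candidate without a
    context-compatible aptamer is discarded and redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[SwitchSpec, PartialTriggerPair, AptamerSpec]] = []
    apt_counter = 0
    for idx in range(n):
        for _attempt in range(200):
            switch = _propose_switch(rng, idx)
            if switch is None:
                continue
            pair = switch.cognate_pair()
            if not _switch_orthogonal(switch, pair, out, -8.0, -25.0):
                continue
            apt = None
            for _ in range(40):
                apt_counter += 1
                candidate = generate_toy_aptamer(
                    seed=seed * 1_000_000 + apt_counter,
                    stem_len=stem_len,
                    ligand=f"ligand_{chr(65 + idx)}",
                )
                if _aptamer_context_ok(candidate, pair):
                    apt = candidate
                    break
            if apt is not None:
                out.append((switch, pair, apt))
                break
        else:
            raise GenerationError(
                f"no compatible switch/aptamer combination for slot {idx + 1}/{n} "
                f"(seed {seed}); try a smaller n or another seed"
            )
    return out


def _aptamer_context_ok(apt: AptamerSpec, pair: PartialTriggerPair) -> bool:
    """Structure-switching penalty in range and trigger-context invariant."""
    pen0 = _closure_penalty(apt.sequence.bases)
    if pen0 is None or not 0.5 <= pen0 <= 10.0:
        return False
    contexts = [
        (pair.b_star + "AAA", "AAA" + pair.a_star),
        (pair.b_star[3:] + "AAA", "AAA" + pair.a_star[:-3]),
        (pair.b_star[1:] + "AAA", "AAA" + pair.a_star[:-1]),
        (pair.b_star[3:] + "AAA", "AAA" + pair.a_star),
        (pair.b_star + "AAA", "AAA" + pair.a_star[:-3]),
    ]
    pens = [_closure_penalty(apt.sequence.bases, f5, f3) for f5, f3 in contexts]
    return all(p is not None and abs(p - pen0) <= 0.02 for p in pens)


def stem_closure_energy(apt: AptamerSpec) -> float:
    """Energy (kcal/mol) of the fully closed lower stem as a model hairpin.

    The two arms are joined by a 4-nt loop and every arm position is
    paired; this isolates the stem's stacking contribution for
    hand-checking variant orderings.
    """
    if apt.stem_len == 0:
        return 0.0
    probe = apt.stem5 + "AAAA" + apt.stem3
    db = "(" * apt.stem_len + "...." + ")" * apt.stem_len
    return thermo.energy_of_structure(probe, db)
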
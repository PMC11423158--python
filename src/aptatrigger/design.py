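"""Apta-trigger assembly and thermodynamic variant scoring.

An apta-trigger inserts a structure-switching aptamer between the two
partial trigger domains of a toehold switch (5'-b* | linker | aptamer |
linker | a*-3', 3-nt linkers by default). The engineering handle is the
aptamer's lower stem: its stability relative to the unmodified aptamer,

    ddG = dG_modified - dG_original   (kcal/mol, positive = destabilized),

is computed by folding each aptamer flanked by 3-nt neutral A-linkers.
Variants with intermediate stability (3 < ddG < 7 kcal/mol) give the
largest dynamic range; stronger stems leak, weaker stems fail to switch.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, replace

import numpy as np

from . import thermo
from .parts import AptamerSpec, PartialTriggerPair, SwitchSpec
from .sequence import NucleicSequence, SequenceError

__all__ = [
    "AptaTriggerDesign",
    "StemVariant",
    "TOO_STRONG",
    "OPTIMAL",
    "TOO_WEAK",
    "DEFAULT_WINDOW",
    "assemble_apta_trigger",
    "compute_ddg",
    "classify_stability",
    "enumerate_stem_variants",
    "trim_partial_triggers",
    "insertion_position_variants",
    "make_cis_construct",
    "parse_design_name",
]

TOO_STRONG = "too_strong"
OPTIMAL = "optimal"
TOO_WEAK = "too_weak"

#: printed stability window (kcal/mol), exclusive at both ends
DEFAULT_WINDOW = (3.0, 7.0)

#: neutral linker base (minimizes spurious pairing)
LINKER_BASE = "A"

_NAME_RE = re.compile(r"^(?P<ligand>.+)_(?P<switch>[A-Za-z]+)(?P<version>\d+)$")


def parse_design_name(name: str) -> tuple[str, str, int]:
    """Split a design name Ligand_SwitchIdVersion into its components."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(
            f"design name {name!r} does not match the Ligand_SwitchIdVersion convention"
        )
    return m["ligand"], m["switch"], int(m["version"])


@dataclass(frozen=True)
class StemVariant:
    """A lower-stem variant scored against the original aptamer."""

    stem5: str
    stem3: str
    dg_modified: float
    dg_original: float

    @property
    def ddg(self) -> float:
        return self.dg_modified - self.dg_original


@dataclass(frozen=True)
class AptaTriggerDesign:
    """An assembled apta-trigger with its ddG score and stability class.

    Immutable; trimming or re-assembly returns new objects. The
    ``aptamer_span`` (0-based, half-open) locates the aptamer within the
    full sequence for bonus-folding.
    """

    name: str
    b_star: str
    linker5: str
    aptamer_variant: AptamerSpec
    linker3: str
    a_star: str
    ddg: float
    stability_class: str
    original: AptamerSpec

    @property
    def full_sequence(self) -> NucleicSequence:
        return NucleicSequence(
            self.name,
            self.b_star + self.linker5 + self.aptamer_variant.sequence.bases
            + self.linker3 + self.a_star,
        )

    @property
    def aptamer_span(self) -> tuple[int, int]:
        start = len(self.b_star) + len(self.linker5)
        return start, start + len(self.aptamer_variant.sequence)

    @property
    def has_aptamer(self) -> bool:
        return True


def compute_ddg(
    variant: AptamerSpec,
    original: AptamerSpec,
    linker_len: int = 3,
    params=None,
) -> StemVariant:
    """Score a stem variant: ddG = dG_modified - dG_original.

    Each aptamer is folded flanked by ``linker_len`` neutral A bases on
    both sides, mirroring how the aptamer sits between trigger domains.
    Both aptamers must share the same core.
    """
    if variant.core.bases != original.core.bases:
        raise SequenceError(
            f"variant {variant.name!r} and original {original.name!r} have "
            "different cores; ddG compares lower-stem variants of one aptamer"
        )
    flank = LINKER_BASE * linker_len
    dg_mod = thermo.fold_mfe(flank + variant.sequence.bases + flank, params).dg
    dg_orig = thermo.fold_mfe(flank + original.sequence.bases + flank, params).dg
    return StemVariant(variant.stem5, variant.stem3, dg_mod, dg_orig)


def classify_stability(
    ddg: float, window: tuple[float, float] = DEFAULT_WINDOW
) -> str:
    """Map a ddG to too_strong / optimal / too_weak.

    The window is exclusive at both ends: ddg <= low is too_strong (stem
    at least as stable as useful, high background), low < ddg < high is
    optimal, ddg >= high is too_weak (stem cannot be rescued by ligand).
    """
    low, high = window
    if low >= high:
        raise ValueError(f"window low {low} must be below high {high}")
    if ddg <= low:
        return TOO_STRONG
    if ddg < high:
        return OPTIMAL
    return TOO_WEAK


def assemble_apta_trigger(
    pair: PartialTriggerPair,
    apt: AptamerSpec,
    linker_len: int = 3,
    original: AptamerSpec | None = None,
    name: str | None = None,
    switch_id: str = "A",
    version: int = 1,
    window: tuple[float, float] = DEFAULT_WINDOW,
    params=None,
) -> AptaTriggerDesign:
    """Assemble 5'-b* | linker | aptamer | linker | a*-3' and score it.

    ``original`` is the unmodified aptamer against which ddG is computed;
    it defaults to ``apt`` itself (ddG = 0 for an unmodified stem).
    """
    if linker_len < 0:
        raise ValueError("linker_len must be >= 0")
    original = original or apt
    sv = compute_ddg(apt, original, params=params)
    ddg = sv.ddg
    if name is None:
        ligand_tag = apt.ligand[:4].capitalize()
        name = f"{ligand_tag}_{switch_id}{version}"
    parse_design_name(name)
    linker = LINKER_BASE * linker_len
    return AptaTriggerDesign(
        name=name,
        b_star=pair.b_star,
        linker5=linker,
        aptamer_variant=apt,
        linker3=linker,
        a_star=pair.a_star,
        ddg=ddg,
        stability_class=classify_stability(ddg, window),
        original=original,
    )


def enumerate_stem_variants(
    apt: AptamerSpec,
    lengths: set[int],
    max_variants: int = 2000,
    seed: int = 0,
    params=None,
) -> list[StemVariant]:
    """Complementary-arm stem variants of an aptamer, sorted by ddG.

    Enumeration is exhaustive over the 6 canonical pair types per stem
    position when the total count fits in ``max_variants``; otherwise a
    seeded uniform sample (without replacement) is scored. Ties in ddG
    break lexicographically on the 5' arm.
    """
    lengths = set(lengths)
    if not lengths:
        raise ValueError("lengths must be non-empty")
    if not lengths <= set(range(1, 9)):
        raise ValueError("stem lengths must lie in 1..8")
    pair_types = ["AU", "UA", "CG", "GC", "GU", "UG"]
    arms: list[tuple[str, str]] = []
    for length in sorted(lengths):
        for combo in itertools.product(pair_types, repeat=length):
            stem5 = "".join(x for x, _ in combo)
            stem3 = "".join(y for _, y in reversed(combo))
            arms.append((stem5, stem3))
    if len(arms) > max_variants:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(arms), size=max_variants, replace=False)
        arms = [arms[i] for i in sorted(idx)]
    variants = [
        compute_ddg(apt.with_stem(s5, s3), apt, params=params) for s5, s3 in arms
    ]
    return sorted(variants, key=lambda v: (v.ddg, v.stem5))


def trim_partial_triggers(
    design: AptaTriggerDesign, n5: int, n3: int
) -> AptaTriggerDesign:
    """Trim the outer ends of the partial trigger domains.

    Removes ``n5`` bases from the 5' (outer) end of b* and ``n3`` from
    the 3' (outer) end of a*; trimming reduces spontaneous (ligand-free)
    switch activation. Returns a new design; the input is unchanged.
    """
    if n5 < 0 or n3 < 0:
        raise ValueError("trim lengths must be >= 0")
    if n5 >= len(design.b_star) or n3 >= len(design.a_star):
        raise SequenceError(
            f"over-trimming: b*({len(design.b_star)}) by {n5}, "
            f"a*({len(design.a_star)}) by {n3}"
        )
    if n5 == 0 and n3 == 0:
        return design
    return replace(
        design,
        name=f"{design.name}_trim{n5}.{n3}",
        b_star=design.b_star[n5:],
        a_star=design.a_star[: len(design.a_star) - n3],
    )


def insertion_position_variants(
    pair: PartialTriggerPair,
    apt: AptamerSpec,
    positions: list[int] | None = None,
    linker_len: int = 3,
    original: AptamerSpec | None = None,
    params=None,
    **assemble_kwargs,
) -> list[AptaTriggerDesign]:
    """Designs splitting the full trigger at different aptamer insertion points.

    The full cognate trigger (b* + a*) is re-divided at each split point;
    the midpoint split is used when no positions are given. The aptamer
    ddG is split-point invariant (the stem is untouched).
    """
    full = pair.full_trigger
    if positions is None:
        positions = [len(full) // 2]
    out = []
    for p in positions:
        if p <= 0 or p >= len(full):
            raise SequenceError(
                f"split point {p} would leave an empty partial trigger domain"
            )
        new_pair = PartialTriggerPair(b_star=full[:p], a_star=full[p:])
        d = assemble_apta_trigger(
            new_pair, apt, linker_len=linker_len, original=original,
            params=params, **assemble_kwargs,
        )
        out.append(replace(d, name=f"{d.name}_pos{p}"))
    return out


def make_cis_construct(
    design: AptaTriggerDesign,
    switch: SwitchSpec,
    tether_len: int = 7,
) -> NucleicSequence:
    """Single-transcript (cis-acting) construct: trigger | tether | switch.

    The unstructured A-tether (7 nt by default) lets strand displacement
    occur in cis. The design must be cognate to the switch: its combined
    trigger domains must target the switch's recognition region.
    """
    if tether_len < 0:
        raise ValueError("tether_len must be >= 0")
    from .sequence import reverse_complement

    target = reverse_complement(design.b_star + design.a_star)
    recognition = switch.sequence.bases[: switch.recognition_length]
    if target not in recognition:
        raise SequenceError(
            f"design {design.name!r} is not cognate to switch {switch.name!r}: "
            "its trigger domains do not match the switch recognition region"
        )
    tether = LINKER_BASE * tether_len
    return NucleicSequence(
        f"{design.name}_cis_{switch.name}",
        design.full_sequence.bases + tether + switch.sequence.bases,
    )
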
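"""Core sequence and secondary-structure types.

All sequences are stored as sense-strand RNA over the alphabet {A, C, G, U};
DNA input (T) is transliterated to U and case is normalized on construction.
Secondary structures use dot-bracket notation: matched parentheses for base
pairs, dots for unpaired bases, no pseudoknots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RNA_ALPHABET = frozenset("ACGU")

#: canonical base pairs: Watson-Crick plus wobble
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
MIN_HAIRPIN = 3

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE_PARTNER = {"A": "U", "U": "A", "C": "G", "G": "U"}


class SequenceError(ValueError):
    """Raised for malformed sequences or structures."""


def normalize_bases(raw: str) -> str:
    """Upper-case a sequence string and transliterate T to U.

    Raises :class:`SequenceError` naming the first offending position if a
    character outside {A, C, G, U, T} (any case) is found.
    """
    bases = raw.upper().replace("T", "U")
    for pos, b in enumerate(bases):
        if b not in RNA_ALPHABET:
            raise SequenceError(
                f"invalid base {b!r} at position {pos} (alphabet is A/C/G/U, "
                "T accepted as DNA input)"
            )
    return bases


def can_pair(x: str, y: str) -> bool:
    return (x, y) in ALLOWED_PAIRS


def reverse_complement(bases: str, wobble: bool = False) -> str:
    """Reverse complement of an RNA string.

    With ``wobble=True``, G is partnered with U instead of C, producing an
    arm that closes through wobble pairs (used by the toy aptamer generator).
    """
    table = _WOBBLE_PARTNER if wobble else _COMPLEMENT
    return "".join(table[b] for b in reversed(bases))


@dataclass(frozen=True)
class NucleicSequence:
    """A validated RNA sequence with a short identifier."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        object.__setattr__(self, "bases", normalize_bases(self.bases))
        if len(self.bases) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)

    def encode(self) -> np.ndarray:
        """Integer encoding (A=0, C=1, G=2, U=3) used by the DP kernels."""
        return np.fromiter((_CODE[b] for b in self.bases), dtype=np.int8)

    def subsequence(self, start: int, stop: int, id: str | None = None) -> "NucleicSequence":
        return NucleicSequence(id or f"{self.id}[{start}:{stop}]", self.bases[start:stop])


def as_sequence(seq: "NucleicSequence | str", id: str = "seq") -> NucleicSequence:
    if isinstance(seq, NucleicSequence):
        return seq
    return NucleicSequence(id, seq)


@dataclass(frozen=True)
class DotBracketStructure:
    """A balanced, pseudoknot-free dot-bracket string."""

    db: str

    def __post_init__(self) -> None:
        stack = []
        for pos, c in enumerate(self.db):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise SequenceError(f"unmatched ')' at position {pos}")
                stack.pop()
            elif c != ".":
                raise SequenceError(f"invalid structure character {c!r} at position {pos}")
        if stack:
            raise SequenceError(f"unmatched '(' at position {stack[-1]}")

    def __len__(self) -> int:
        return len(self.db)

    def pair_table(self) -> np.ndarray:
        """Partner index per position, -1 for unpaired."""
        pt = np.full(len(self.db), -1, dtype=np.int64)
        stack: list[int] = []
        for pos, c in enumerate(self.db):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                i = stack.pop()
                pt[i] = pos
                pt[pos] = i
        return pt

    def pairs(self) -> list[tuple[int, int]]:
        pt = self.pair_table()
        return [(i, int(j)) for i, j in enumerate(pt) if j > i]

    @staticmethod
    def from_pairs(n: int, pairs: "list[tuple[int, int]] | dict[int, int]") -> "DotBracketStructure":
        chars = ["."] * n
        items = pairs.items() if isinstance(pairs, dict) else pairs
        for i, j in items:
            if i > j:
                i, j = j, i
            chars[i], chars[j] = "(", ")"
        return DotBracketStructure("".join(chars))


def validate_structure(seq: NucleicSequence, db: DotBracketStructure) -> np.ndarray:
    """Check a structure against its sequence; return the pair table.

    Enforces equal length, canonical pairs and the minimum hairpin loop.
    """
    if len(db) != len(seq):
        raise SequenceError(
            f"structure length {len(db)} != sequence length {len(seq)} for {seq.id!r}"
        )
    pt = db.pair_table()
    for i, j in enumerate(pt):
        if j > i:
            if not can_pair(seq.bases[i], seq.bases[j]):
                raise SequenceError(
                    f"invalid pair {seq.bases[i]}{seq.bases[j]} at positions ({i}, {j})"
                )
            if j - i - 1 < MIN_HAIRPIN:
                raise SequenceError(
                    f"hairpin loop shorter than {MIN_HAIRPIN} at pair ({i}, {j})"
                )
    return pt
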
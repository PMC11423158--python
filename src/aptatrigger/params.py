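"""Nearest-neighbor free-energy parameter set.

Parameters are shipped as versioned TSV package data (kcal/mol at 37 C,
1.0 M Na+) and converted to integer decacalories (1 unit = 0.01 kcal/mol)
at load time. All folding arithmetic is integer, so the dynamic program,
its traceback, explicit structure evaluation and the brute-force
enumeration oracle agree exactly, with no float-ordering ambiguity.

Stack energies are stored in a 6x6 matrix indexed by pair type
(AU, UA, CG, GC, GU, UG). The table is symmetrized under strand reversal,
stack[(X,Y),(W,Z)] == stack[(Z,W),(Y,X)], which also makes intermolecular
duplex energies independent of strand order.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

#: pair-type order used throughout the integer kernels
PAIR_ORDER = ("AU", "UA", "CG", "GC", "GU", "UG")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

#: PAIR_INDEX[code(x), code(y)] -> 0..5, or -1 if x:y cannot pair
PAIR_INDEX = np.full((4, 4), -1, dtype=np.int8)
for _k, _p in enumerate(PAIR_ORDER):
    PAIR_INDEX[_BASE_CODE[_p[0]], _BASE_CODE[_p[1]]] = _k

#: maximum loop/sequence size supported by the pre-extrapolated loop tables
MAX_TABLE = 2048


class ParameterError(ValueError):
    """Raised for malformed or physically inconsistent parameter tables."""


def _dcal(value: float) -> int:
    return int(round(value * 100.0))


@dataclass(frozen=True)
class EnergyParameters:
    """Integer-decacalorie nearest-neighbor parameter set at 37 C."""

    version: str
    stack: np.ndarray          # (6, 6) int64, dcal
    hairpin: np.ndarray        # (MAX_TABLE,) int64, index = loop size
    bulge: np.ndarray
    internal: np.ndarray
    terminal: np.ndarray       # (6,) int64, helix-end penalty per pair type
    ml_closing: int
    ml_unpaired: int
    ml_branch: int
    internal_asym: int
    internal_asym_max: int
    duplex_init: int
    min_hairpin: int
    max_loop: int
    rt: float                  # kcal/mol at 310.15 K

    def __post_init__(self) -> None:
        wc = self.stack[:4, :4]
        if not (wc < 0).all():
            raise ParameterError("all Watson-Crick stack energies must be < 0")
        if self.rt <= 0:
            raise ParameterError("rt must be positive")
        for name in ("hairpin", "bulge", "internal"):
            tab = getattr(self, name)
            if (tab[tab < np.iinfo(np.int64).max] < 0).any():
                raise ParameterError(f"{name} loop penalties must be positive")


def _extrapolate(tab_sizes: dict[int, int], min_size: int, lxc: float, rt: float) -> np.ndarray:
    """Tabulated loop penalties extended by a Jacobson-Stockmayer log term."""
    out = np.full(MAX_TABLE, np.iinfo(np.int64).max // 4, dtype=np.int64)
    n_max = max(tab_sizes)
    for n, v in tab_sizes.items():
        out[n] = v
    anchor = tab_sizes[n_max]
    for n in range(n_max + 1, MAX_TABLE):
        out[n] = anchor + _dcal(lxc * rt * math.log(n / n_max))
    return out


def load_parameters(path: str | Path) -> EnergyParameters:
    """Parse a parameter TSV file into an :class:`EnergyParameters`."""
    stacks: dict[tuple[int, int], int] = {}
    loops: dict[str, dict[int, int]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    misc: dict[str, float] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("category\t"):
            continue
        try:
            category, key, value = line.split("\t")
        except ValueError as exc:
            raise ParameterError(f"malformed line {lineno}: {line!r}") from exc
        if category == "stack":
            p1 = _pair_idx(key[0], key[1], lineno)
            p2 = _pair_idx(key[2], key[3], lineno)
            e = _dcal(float(value))
            # strand-reversal partner of (p1, p2)
            q1, q2 = _FLIP[p2], _FLIP[p1]
            for a, b in ((p1, p2), (q1, q2)):
                if stacks.setdefault((a, b), e) != e:
                    raise ParameterError(
                        f"conflicting stack entry {key} at line {lineno}"
                    )
        elif category in loops:
            loops[category][int(key)] = _dcal(float(value))
        elif category == "misc":
            misc[key] = float(value)
        else:
            raise ParameterError(f"unknown category {category!r} at line {lineno}")

    if len(stacks) != 36:
        missing = 36 - len(stacks)
        raise ParameterError(f"stack table incomplete: {missing} entries missing")
    stack = np.zeros((6, 6), dtype=np.int64)
    for (a, b), e in stacks.items():
        stack[a, b] = e

    rt = misc["rt"]
    lxc = misc["lxc"]
    hairpin = _extrapolate(loops["hairpin"], 3, lxc, rt)
    bulge = _extrapolate(loops["bulge"], 1, lxc, rt)
    internal = _extrapolate(loops["internal"], 2, lxc, rt)

    term_pen = _dcal(misc["terminal_au"])
    terminal = np.array(
        [term_pen if p not in ("CG", "GC") else 0 for p in PAIR_ORDER], dtype=np.int64
    )
    return EnergyParameters(
        version=Path(path).stem.replace("rna_nn_params_", ""),
        stack=stack,
        hairpin=hairpin,
        bulge=bulge,
        internal=internal,
        terminal=terminal,
        ml_closing=_dcal(misc["ml_closing"]),
        ml_unpaired=_dcal(misc["ml_unpaired"]),
        ml_branch=_dcal(misc["ml_branch"]),
        internal_asym=_dcal(misc["internal_asym"]),
        internal_asym_max=_dcal(misc["internal_asym_max"]),
        duplex_init=_dcal(misc["duplex_init"]),
        min_hairpin=int(misc["min_hairpin"]),
        max_loop=int(misc["max_loop"]),
        rt=rt,
    )


_FLIP = np.array([1, 0, 3, 2, 5, 4], dtype=np.int64)  # AU<->UA, CG<->GC, GU<->UG


def _pair_idx(x: str, y: str, lineno: int) -> int:
    try:
        return PAIR_ORDER.index(x + y)
    except ValueError as exc:
        raise ParameterError(f"non-canonical pair {x}{y} at line {lineno}") from exc


@lru_cache(maxsize=None)
def default_parameters() -> EnergyParameters:
    """The packaged parameter table (version v1)."""
    ref = importlib.resources.files("aptatrigger") / "data" / "rna_nn_params_v1.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_parameters(path)
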
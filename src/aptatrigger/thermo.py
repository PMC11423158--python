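"""Nearest-neighbor RNA thermodynamics: evaluation, MFE folding, duplexes.

The engine is self-contained: a Turner-style parameter table (37 C, 1 M
Na+) drives a Zuker dynamic program with deterministic traceback, an
explicit loop-decomposition evaluator, an intermolecular duplex DP and an
exhaustive enumeration oracle for short sequences. Energies are computed
in integer decacalories internally and reported as kcal/mol floats, so
`energy_of_structure(seq, fold_mfe(seq).structure) == fold_mfe(seq).dg`
holds exactly.

Ligand binding to an aptamer is modelled as a soft constraint: a
(negative) energy bonus granted to every structure that forms the
aptamer's closing lower-stem pair (:func:`fold_with_aptamer_bonus`),
following the two-state population-shift picture in which the ligand
stabilizes the binding-competent conformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import PAIR_INDEX, EnergyParameters, default_parameters
from .sequence import (
    DotBracketStructure,
    NucleicSequence,
    SequenceError,
    as_sequence,
    validate_structure,
)

__all__ = [
    "FoldResult",
    "energy_of_structure",
    "fold_mfe",
    "fold_with_aptamer_bonus",
    "fold_constrained_pair",
    "enumerate_structures",
    "duplex_mfe",
    "clear_fold_cache",
]

#: default maximum length accepted by the enumeration oracle
ENUMERATION_MAX_LEN = 22

#: dominating pair bonus (dcal) used to force a closing pair
_FORCE_BONUS = -10_000_000


@dataclass(frozen=True)
class FoldResult:
    """An MFE structure with its free energy in kcal/mol.

    ``dg`` includes ``bonus`` whenever ``bonus_pair`` is formed in
    ``structure``; with no bonus, ``dg`` equals
    :func:`energy_of_structure` of the reported structure exactly.
    """

    sequence: NucleicSequence
    structure: DotBracketStructure
    dg: float
    bonus: float = 0.0
    bonus_pair: tuple[int, int] | None = None

    @property
    def bonus_applied(self) -> bool:
        if self.bonus_pair is None:
            return False
        i, j = self.bonus_pair
        pt = self.structure.pair_table()
        return pt[i] == j


def _param_args(params: EnergyParameters):
    return (
        PAIR_INDEX,
        params.stack,
        params.hairpin,
        params.bulge,
        params.internal,
        params.terminal,
        np.int64(params.ml_closing),
        np.int64(params.ml_unpaired),
        np.int64(params.ml_branch),
        np.int64(params.internal_asym),
        np.int64(params.internal_asym_max),
        np.int64(params.min_hairpin),
        np.int64(params.max_loop),
    )


def energy_of_structure(
    seq: NucleicSequence | str,
    db: DotBracketStructure | str,
    params: EnergyParameters | None = None,
) -> float:
    """Free energy (kcal/mol) of a given structure on a given sequence.

    The structure is decomposed into its loops (hairpins, stacks, bulges,
    internal loops, multiloops, exterior loop) and each loop is priced by
    the nearest-neighbor table. The open chain scores exactly 0.
    """
    seq = as_sequence(seq)
    if isinstance(db, str):
        db = DotBracketStructure(db)
    pt = validate_structure(seq, db)
    params = params or default_parameters()
    return _energy_from_pt(seq.encode(), pt, params) / 100.0


def _energy_from_pt(s: np.ndarray, pt: np.ndarray, params: EnergyParameters) -> int:
    """Integer (dcal) loop-decomposition energy; pt assumed valid."""
    pidx = PAIR_INDEX
    stack, bulge, internal, terminal = (
        params.stack, params.bulge, params.internal, params.terminal,
    )
    total = 0
    n = len(s)
    # exterior branches pay helix-end penalties only
    i = 0
    while i < n:
        j = pt[i]
        if j > i:
            total += int(terminal[pidx[s[i], s[j]]])
            i = j + 1
        else:
            i += 1
    for i in range(n):
        j = pt[i]
        if j <= i:
            continue
        # direct children of (i, j)
        children = []
        k = i + 1
        while k < j:
            l = pt[k]
            if l > k:
                children.append((k, l))
                k = l + 1
            else:
                k += 1
        p = pidx[s[i], s[j]]
        if not children:
            total += int(_kernels.hairpin_energy(p, j - i - 1, params.hairpin, terminal))
        elif len(children) == 1:
            k, l = children[0]
            q = pidx[s[k], s[l]]
            total += int(
                _kernels.loop2_energy(
                    p, q, k - i - 1, j - l - 1, stack, bulge, internal,
                    terminal, np.int64(params.internal_asym),
                    np.int64(params.internal_asym_max),
                )
            )
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            e = params.ml_closing + params.ml_branch * (1 + len(children))
            e += params.ml_unpaired * unpaired
            e += int(terminal[p])
            for k, l in children:
                e += int(terminal[pidx[s[k], s[l]]])
            total += e
    return total


# --- MFE folding ----------------------------------------------------------

_fold_cache: dict[tuple, FoldResult] = {}


def clear_fold_cache() -> None:
    _fold_cache.clear()


def _fold(seq: NucleicSequence, params: EnergyParameters,
          bonus_pair: tuple[int, int] | None, bonus_dcal: int) -> FoldResult:
    key = (seq.bases, params.version, bonus_pair, bonus_dcal)
    hit = _fold_cache.get(key)
    if hit is not None:
        return hit
    s = seq.encode()
    n = len(s)
    bi, bj = bonus_pair if bonus_pair is not None else (-1, -1)
    pargs = _param_args(params)
    if n <= params.min_hairpin + 1:
        result = FoldResult(seq, DotBracketStructure("." * n), 0.0,
                            bonus_dcal / 100.0, bonus_pair)
    else:
        args = (
            s, pargs[0], pargs[1], pargs[2], pargs[3], pargs[4], pargs[5],
            pargs[6], pargs[7], pargs[8], pargs[9], pargs[10], pargs[11],
            pargs[12], np.int64(bi), np.int64(bj), np.int64(bonus_dcal),
        )
        V, WM, U = _kernels.fill_matrices(*args)
        dg_dcal = int(U[0])
        pt, ok = _kernels.traceback(*args, V, WM, U)
        if not ok:
            raise RuntimeError(
                f"traceback inconsistency for {seq.id!r}; this is a bug"
            )
        structure = DotBracketStructure.from_pairs(
            n, {int(i): int(j) for i, j in enumerate(pt) if j > i}
        )
        result = FoldResult(
            seq, structure, dg_dcal / 100.0, bonus_dcal / 100.0, bonus_pair
        )
    _fold_cache[key] = result
    return result


def fold_mfe(seq: NucleicSequence | str,
             params: EnergyParameters | None = None) -> FoldResult:
    """Minimum-free-energy pseudoknot-free structure by dynamic programming.

    The open chain (energy 0) is always available, so ``dg <= 0``.
    Traceback is deterministic; repeated calls are bit-identical.
    """
    seq = as_sequence(seq)
    return _fold(seq, params or default_parameters(), None, 0)


def fold_with_aptamer_bonus(
    seq: NucleicSequence | str,
    aptamer_span: tuple[int, int],
    bonus: float,
    params: EnergyParameters | None = None,
) -> FoldResult:
    """MFE fold with an energy bonus for closing the aptamer's lower stem.

    ``aptamer_span`` is a 0-based half-open interval; the span's closing
    pair is (start, stop - 1). Any structure forming that pair receives
    ``bonus`` (kcal/mol, <= 0), emulating ligand stabilization of the
    binding-competent conformation. With ``bonus = 0`` the result is
    identical to :func:`fold_mfe`.
    """
    seq = as_sequence(seq)
    start, stop = aptamer_span
    if not (0 <= start < stop <= len(seq)):
        raise SequenceError(
            f"aptamer span ({start}, {stop}) out of bounds for length {len(seq)}"
        )
    if bonus > 0:
        raise ValueError(f"bonus must be <= 0 kcal/mol, got {bonus}")
    pair = (start, stop - 1)
    return _fold(seq, params or default_parameters(), pair, int(round(bonus * 100)))


def fold_constrained_pair(
    seq: NucleicSequence | str,
    i: int,
    j: int,
    params: EnergyParameters | None = None,
) -> FoldResult | None:
    """Best structure in which positions i and j pair, or None if impossible.

    Implemented with a dominating pair bonus that is subtracted back out;
    the returned ``dg`` is the unmodified structural energy.
    """
    seq = as_sequence(seq)
    params = params or default_parameters()
    res = _fold(seq, params, (i, j), _FORCE_BONUS)
    pt = res.structure.pair_table()
    if pt[i] != j:
        return None
    # recompute the structural energy exactly (no big-bonus round-off)
    dg = _energy_from_pt(seq.encode(), pt, params) / 100.0
    return FoldResult(res.sequence, res.structure, dg)


# --- exhaustive enumeration oracle ---------------------------------------


def enumerate_structures(
    seq: NucleicSequence | str,
    max_len: int = ENUMERATION_MAX_LEN,
    params: EnergyParameters | None = None,
) -> list[tuple[DotBracketStructure, float]]:
    """Every valid pseudoknot-free structure with its energy.

    Brute-force oracle for verifying the dynamic program; refuses
    sequences longer than ``max_len`` to guard against combinatorial
    blow-up. The open chain is always included.
    """
    seq = as_sequence(seq)
    if len(seq) > max_len:
        raise ValueError(
            f"sequence {seq.id!r} has length {len(seq)} > max_len={max_len}; "
            "enumeration is exponential and refused"
        )
    params = params or default_parameters()
    s = seq.encode()
    n = len(s)
    min_hp = params.min_hairpin

    def gen(i: int, j: int):
        """Yield pair tuples for region [i, j]."""
        if i > j:
            yield ()
            return
        # position i unpaired
        for rest in gen(i + 1, j):
            yield rest
        # position i paired with k
        for k in range(i + min_hp + 1, j + 1):
            if PAIR_INDEX[s[i], s[k]] < 0:
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield ((i, k),) + inner + outer

    out = []
    for pairs in gen(0, n - 1):
        pt = np.full(n, -1, dtype=np.int64)
        for a, b in pairs:
            pt[a] = b
            pt[b] = a
        e = _energy_from_pt(s, pt, params)
        out.append((DotBracketStructure.from_pairs(n, dict(pairs)), e / 100.0))
    return out


# --- intermolecular duplexes ----------------------------------------------


def duplex_mfe(
    seq_a: NucleicSequence | str,
    seq_b: NucleicSequence | str,
    params: EnergyParameters | None = None,
) -> tuple[float, dict[int, int]]:
    """Best intermolecular hybridization energy and its base-pair map.

    Only inter-strand pairs are considered (stacks, bulges and internal
    loops within the duplex), plus a fixed duplex-initiation penalty and
    helix-end penalties. Returns (0.0, {}) when no duplex with negative
    free energy exists. Symmetric in its arguments.
    """
    a = as_sequence(seq_a, "a")
    b = as_sequence(seq_b, "b")
    params = params or default_parameters()
    sa, sb = a.encode(), b.encode()
    D = _kernels.duplex_fill(
        sa, sb, PAIR_INDEX, params.stack, params.bulge, params.internal,
        params.terminal, np.int64(params.internal_asym),
        np.int64(params.internal_asym_max), np.int64(params.duplex_init),
        np.int64(params.max_loop),
    )
    best = 0
    bi = bj = -1
    na, nb = len(sa), len(sb)
    for i in range(na):
        for j in range(nb):
            if D[i, j] >= _kernels.INF:
                continue
            e = int(D[i, j]) + int(params.terminal[PAIR_INDEX[sa[i], sb[j]]])
            if e < best:
                best, bi, bj = e, i, j
    if bi < 0:
        return 0.0, {}
    # walk the DP back to recover the pair map
    pairs = {bi: bj}
    i, j = bi, bj
    while True:
        p = PAIR_INDEX[sa[i], sb[j]]
        target = int(D[i, j])
        if target == params.duplex_init + int(params.terminal[p]):
            break
        found = False
        for k in range(i - 1, -1, -1):
            n1 = i - k - 1
            if n1 > params.max_loop:
                break
            for l in range(j + 1, nb):
                n2 = l - j - 1
                if n1 + n2 > params.max_loop:
                    break
                if D[k, l] >= _kernels.INF:
                    continue
                q = PAIR_INDEX[sa[k], sb[l]]
                e = int(D[k, l]) + int(
                    _kernels.loop2_energy(
                        q, p, n1, n2, params.stack, params.bulge,
                        params.internal, params.terminal,
                        np.int64(params.internal_asym),
                        np.int64(params.internal_asym_max),
                    )
                )
                if e == target:
                    pairs[k] = l
                    i, j = k, l
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - would indicate a kernel bug
            raise RuntimeError("duplex traceback inconsistency")
    return best / 100.0, pairs
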
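"""Integer dynamic-programming kernels for secondary-structure prediction.

Zuker-style minimum-free-energy recursions over integer decacalorie
energies, JIT-compiled with numba. Conventions:

* sequences are int8 arrays (A=0, C=1, G=2, U=3);
* ``V[i, j]`` is the best energy of the fragment i..j given that (i, j)
  pair; ``WM[i, j]`` the best energy of a multiloop segment i..j containing
  at least one branch; ``U[i]`` the best energy of the suffix i..n-1 in the
  exterior loop;
* an optional single-pair bonus (bi, bj, bonus) is added into ``V[bi, bj]``,
  rewarding every structure that forms that pair;
* traceback is deterministic: at every choice point the first matching
  candidate wins, scanning pairs by smallest i then smallest j, with
  hairpin, then two-loop, then multiloop decompositions tried in order.

The same primitive loop-energy functions are reused by the explicit
structure evaluator and the duplex kernel, so every code path prices a
given loop identically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.int64(2) ** 40


@njit(cache=False)
def loop2_energy(p1, p2, n1, n2, stack, bulge, internal, terminal, asym, asym_max):
    """Energy of the loop between closing pair p1 and inner pair p2.

    n1/n2 are the unpaired counts on the two sides: a stack (0/0), a bulge
    (one side 0) or an internal loop. Single-base bulges retain the stack
    of the flanking pairs; larger loops pay helix-end penalties instead.
    """
    if n1 == 0 and n2 == 0:
        return stack[p1, p2]
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        e = bulge[n]
        if n == 1:
            e += stack[p1, p2]
        else:
            e += terminal[p1] + terminal[p2]
        return e
    d = n1 - n2
    if d < 0:
        d = -d
    a = asym * d
    if a > asym_max:
        a = asym_max
    return internal[n] + a + terminal[p1] + terminal[p2]


@njit(cache=False)
def hairpin_energy(p, size, hairpin, terminal):
    return hairpin[size] + terminal[p]


@njit(cache=False)
def fill_matrices(s, pidx, stack, hairpin, bulge, internal, terminal,
                  ml_a, ml_b, ml_c, asym, asym_max, min_hp, max_loop,
                  bi, bj, bonus):
    n = s.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    for span in range(min_hp + 1, n):
        for i in range(0, n - span):
            j = i + span
            p = pidx[s[i], s[j]]
            if p >= 0:
                best = hairpin_energy(p, j - i - 1, hairpin, terminal)
                # stacks, bulges, internal loops
                for k in range(i + 1, j - 1):
                    n1 = k - i - 1
                    if n1 > max_loop:
                        break
                    for l in range(j - 1, k, -1):
                        n2 = j - l - 1
                        if n1 + n2 > max_loop:
                            break
                        if V[k, l] >= INF:
                            continue
                        q = pidx[s[k], s[l]]
                        e = loop2_energy(p, q, n1, n2, stack, bulge, internal,
                                         terminal, asym, asym_max) + V[k, l]
                        if e < best:
                            best = e
                # multiloop closed by (i, j): >= 2 branches inside
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        e = ml_a + ml_c + terminal[p] + WM[i + 1, k] + WM[k + 1, j - 1]
                        if e < best:
                            best = e
                if i == bi and j == bj:
                    best += bonus
                V[i, j] = best
            # multiloop segment i..j
            best = INF
            if V[i, j] < INF:
                best = V[i, j] + ml_c + terminal[p]
            if WM[i + 1, j] < INF:
                e = WM[i + 1, j] + ml_b
                if e < best:
                    best = e
            if WM[i, j - 1] < INF:
                e = WM[i, j - 1] + ml_b
                if e < best:
                    best = e
            for k in range(i + 1, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    e = WM[i, k] + WM[k + 1, j]
                    if e < best:
                        best = e
            WM[i, j] = best
    U = np.zeros(n + 1, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        best = U[i + 1]
        for j in range(i + min_hp + 1, n):
            if V[i, j] < INF:
                e = V[i, j] + terminal[pidx[s[i], s[j]]] + U[j + 1]
                if e < best:
                    best = e
        U[i] = best
    return V, WM, U


@njit(cache=False)
def traceback(s, pidx, stack, hairpin, bulge, internal, terminal,
              ml_a, ml_b, ml_c, asym, asym_max, min_hp, max_loop,
              bi, bj, bonus, V, WM, U):
    """Recover one optimal structure as a pair table (-1 = unpaired).

    Returns (pair_table, ok_flag); ok_flag is 0 on internal inconsistency,
    which indicates a bug rather than a user error.
    """
    n = s.shape[0]
    pt = np.full(n, -1, dtype=np.int64)
    # work stack of (i, j, mode); mode 0 = V, 1 = WM
    cap = 4 * n + 16
    st_i = np.empty(cap, dtype=np.int64)
    st_j = np.empty(cap, dtype=np.int64)
    st_m = np.empty(cap, dtype=np.int64)
    sp = 0

    i = 0
    while i < n:
        paired = False
        for j in range(i + min_hp + 1, n):
            if V[i, j] < INF and U[i] == V[i, j] + terminal[pidx[s[i], s[j]]] + U[j + 1]:
                st_i[sp], st_j[sp], st_m[sp] = i, j, 0
                sp += 1
                i = j + 1
                paired = True
                break
        if not paired:
            if U[i] != U[i + 1]:
                return pt, 0
            i += 1

    while sp > 0:
        sp -= 1
        i, j, mode = st_i[sp], st_j[sp], st_m[sp]
        if mode == 0:
            pt[i] = j
            pt[j] = i
            p = pidx[s[i], s[j]]
            target = V[i, j]
            if i == bi and j == bj:
                target -= bonus
            if target == hairpin_energy(p, j - i - 1, hairpin, terminal):
                continue
            done = False
            for k in range(i + 1, j - 1):
                n1 = k - i - 1
                if n1 > max_loop:
                    break
                for l in range(j - 1, k, -1):
                    n2 = j - l - 1
                    if n1 + n2 > max_loop:
                        break
                    if V[k, l] >= INF:
                        continue
                    q = pidx[s[k], s[l]]
                    e = loop2_energy(p, q, n1, n2, stack, bulge, internal,
                                     terminal, asym, asym_max) + V[k, l]
                    if e == target:
                        st_i[sp], st_j[sp], st_m[sp] = k, l, 0
                        sp += 1
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF and \
                        target == ml_a + ml_c + terminal[p] + WM[i + 1, k] + WM[k + 1, j - 1]:
                    st_i[sp], st_j[sp], st_m[sp] = i + 1, k, 1
                    sp += 1
                    st_i[sp], st_j[sp], st_m[sp] = k + 1, j - 1, 1
                    sp += 1
                    done = True
                    break
            if not done:
                return pt, 0
        else:
            ii = i
            while ii <= j:
                found = False
                for k in range(ii + min_hp + 1, j + 1):
                    if V[ii, k] >= INF:
                        continue
                    val = V[ii, k] + ml_c + terminal[pidx[s[ii], s[k]]]
                    if k == j and WM[ii, j] == val:
                        st_i[sp], st_j[sp], st_m[sp] = ii, k, 0
                        sp += 1
                        ii = j + 1
                        found = True
                        break
                    if WM[ii, j] == val + ml_b * (j - k):
                        st_i[sp], st_j[sp], st_m[sp] = ii, k, 0
                        sp += 1
                        ii = j + 1
                        found = True
                        break
                    if k < j and WM[k + 1, j] < INF and WM[ii, j] == val + WM[k + 1, j]:
                        st_i[sp], st_j[sp], st_m[sp] = ii, k, 0
                        sp += 1
                        ii = k + 1
                        found = True
                        break
                if not found:
                    if ii >= j or WM[ii, j] != WM[ii + 1, j] + ml_b:
                        return pt, 0
                    ii += 1
    return pt, 1


@njit(cache=False)
def duplex_fill(sa, sb, pidx, stack, bulge, internal, terminal,
                asym, asym_max, duplex_init, max_loop):
    """Intermolecular hybridization DP.

    D[i, j] = best energy of a duplex whose 3'-most pair on strand A is
    (A_i, B_j), including initiation and the far-end helix-end penalty but
    not the near-end one.
    """
    na = sa.shape[0]
    nb = sb.shape[0]
    D = np.full((na, nb), INF, dtype=np.int64)
    for i in range(na):
        for j in range(nb - 1, -1, -1):
            p = pidx[sa[i], sb[j]]
            if p < 0:
                continue
            best = duplex_init + terminal[p]
            for k in range(i - 1, -1, -1):
                n1 = i - k - 1
                if n1 > max_loop:
                    break
                for l in range(j + 1, nb):
                    n2 = l - j - 1
                    if n1 + n2 > max_loop:
                        break
                    if D[k, l] >= INF:
                        continue
                    q = pidx[sa[k], sb[l]]
                    e = D[k, l] + loop2_energy(q, p, n1, n2, stack, bulge,
                                               internal, terminal, asym, asym_max)
                    if e < best:
                        best = e
            D[i, j] = best
    return D
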
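"""Numba-accelerated dynamic-programming kernels.

All kernels operate on integer-encoded sequences / precomputed score
matrices so the surrounding modules keep full control over alphabets and
scoring. Tie-breaking is deterministic everywhere: diagonal moves are
preferred over vertical (consume query/profile A) over horizontal.

Gap convention: a gap of length k costs ``open + k * extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def sw_affine(q, s, subst, gap_open, gap_extend):
    """Optimal local alignment score + traceback (Gotoh).

    Parameters: integer-encoded sequences, substitution matrix, affine
    penalties (positive). Returns ``(score, ops, n_ops, qend, send)``
    where ``ops`` holds the traceback moves from the end cell backwards
    (1 = diagonal, 2 = up/consume query, 3 = left/consume subject) and
    ``qend``/``send`` are 1-based end coordinates. ``n_ops == 0`` means
    the empty alignment (best score <= 0).
    """
    n, m = len(q), len(s)
    go = gap_open + gap_extend  # cost of opening a length-1 gap
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 from H, 0 from E
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eh = H[i, j - 1] - go
            ee = E[i, j - 1] - gap_extend
            if eh >= ee:
                E[i, j] = eh
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fh = H[i - 1, j] - go
            ff = F[i - 1, j] - gap_extend
            if fh >= ff:
                F[i, j] = fh
                ptrF[i, j] = 1
            else:
                F[i, j] = ff
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + subst[q[i - 1], s[j - 1]]
            # priority: diagonal > up (F) > left (E) > stop
            val = 0.0
            ptr = 0
            if diag >= val and diag >= F[i, j] and diag >= E[i, j]:
                val = diag
                ptr = 1
            elif F[i, j] >= val and F[i, j] >= E[i, j]:
                val = F[i, j]
                ptr = 2
            elif E[i, j] >= val:
                val = E[i, j]
                ptr = 3
            H[i, j] = val
            ptrH[i, j] = ptr
            if val > best:
                best = val
                bi = i
                bj = j
    ops = np.zeros(n + m, dtype=np.int8)
    k = 0
    if best <= 0.0:
        return 0.0, ops, 0, 0, 0
    i, j = bi, bj
    state = 0  # 0 in H, 2 in F, 3 in E
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                ops[k] = 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            ops[k] = 2
            k += 1
            if ptrF[i, j] == 1:
                state = 0
            i -= 1
        else:
            ops[k] = 3
            k += 1
            if ptrE[i, j] == 1:
                state = 0
            j -= 1
    return best, ops, k, bi, bj


@njit(cache=True)
def nw_affine_profile(S, gap_open, gap_extend):
    """Global alignment of two profiles given a column-score matrix.

    ``S[i, j]`` scores profile-A column i against profile-B column j.
    End gaps are penalized like internal ones. Returns ``(score, ops,
    n_ops)`` with traceback moves from the end backwards (1 = diagonal,
    2 = consume A, 3 = consume B).
    """
    n, m = S.shape
    go = gap_open + gap_extend
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)  # gap in A (consume B)
    F = np.full((n + 1, m + 1), NEG)  # gap in B (consume A)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -(gap_open + j * gap_extend)
        ptrE[0, j] = 1 if j == 1 else 0
        H[0, j] = E[0, j]
        ptrH[0, j] = 3
    for i in range(1, n + 1):
        F[i, 0] = -(gap_open + i * gap_extend)
        ptrF[i, 0] = 1 if i == 1 else 0
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eh = H[i, j - 1] - go
            ee = E[i, j - 1] - gap_extend
            if eh >= ee:
                E[i, j] = eh
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fh = H[i - 1, j] - go
            ff = F[i - 1, j] - gap_extend
            if fh >= ff:
                F[i, j] = fh
                ptrF[i, j] = 1
            else:
                F[i, j] = ff
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            if diag >= F[i, j] and diag >= E[i, j]:
                H[i, j] = diag
                ptrH[i, j] = 1
            elif F[i, j] >= E[i, j]:
                H[i, j] = F[i, j]
                ptrH[i, j] = 2
            else:
                H[i, j] = E[i, j]
                ptrH[i, j] = 3
    ops = np.zeros(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                ops[k] = 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            ops[k] = 2
            k += 1
            if ptrF[i, j] == 1:
                state = 0
            i -= 1
        else:
            ops[k] = 3
            k += 1
            if ptrE[i, j] == 1:
                state = 0
            j -= 1
    return H[n, m], ops, k


@njit(cache=True, inline="always")
def _lse2(a, b):
    """log2(2**a + 2**b), safe against -inf sentinels."""
    if a < b:
        a, b = b, a
    if b <= NEG / 2.0:
        return a
    return a + np.log2(1.0 + 2.0 ** (b - a))


@njit(cache=True)
def hmm_glocal(obs, mlo, ilo, t, forward):
    """Glocal (full-model, free-flanks) Viterbi or forward bit score.

    ``obs``: integer-encoded sequence (index 20 = unknown, already 0 in
    the log-odds tables). ``mlo``/``ilo``: (L+1, 21) match/insert
    emission log2-odds (match row 0 unused; insert rows 0..L).
    ``t``: (L+1, 7) log2 transition table, columns
    [MM, MI, MD, IM, II, DM, DD]; node 0 holds the begin wiring
    (B->M1, B->I0, B->D1) and node L the end wiring (M->E in MM,
    I->E in IM, D->E in DM). Flank residues are emitted at background
    (0 bits); entry and exit positions are unconstrained.
    """
    n = len(obs)
    L = mlo.shape[0] - 1
    VM = np.full((n + 1, L + 1), NEG)
    VI = np.full((n + 1, L + 1), NEG)
    VD = np.full((n + 1, L + 1), NEG)
    for j in range(n + 1):
        VM[j, 0] = 0.0  # begin state, reachable after any free N-flank
    # row 0: no residues consumed yet; only delete chains possible
    for k in range(1, L + 1):
        a = VM[0, k - 1] + t[k - 1, 2]
        b = VD[0, k - 1] + t[k - 1, 6]
        VD[0, k] = _lse2(a, b) if forward else max(a, b)
    for j in range(1, n + 1):
        x = obs[j - 1]
        for k in range(1, L + 1):
            a = VM[j - 1, k - 1] + t[k - 1, 0]
            b = VI[j - 1, k - 1] + t[k - 1, 3]
            c = VD[j - 1, k - 1] + t[k - 1, 5]
            if forward:
                VM[j, k] = mlo[k, x] + _lse2(_lse2(a, b), c)
            else:
                best = a
                if b > best:
                    best = b
                if c > best:
                    best = c
                VM[j, k] = mlo[k, x] + best
        for k in range(L + 1):
            a = VM[j - 1, k] + t[k, 1]
            b = VI[j - 1, k] + t[k, 4]
            VI[j, k] = ilo[k, x] + (_lse2(a, b) if forward else max(a, b))
        for k in range(1, L + 1):
            a = VM[j, k - 1] + t[k - 1, 2]
            b = VD[j, k - 1] + t[k - 1, 6]
            VD[j, k] = _lse2(a, b) if forward else max(a, b)
    total = NEG
    for j in range(n + 1):
        a = VM[j, L] + t[L, 0]
        b = VI[j, L] + t[L, 3]
        c = VD[j, L] + t[L, 5]
        endj = _lse2(_lse2(a, b), c) if forward else max(a, max(b, c))
        total = _lse2(total, endj) if forward else max(total, endj)
    return total
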
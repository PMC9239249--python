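"""Numba kernels: affine-gap Smith-Waterman and profile-HMM forward/Viterbi.

Conventions (shared with the pure-Python test oracles):

* Gap costs: the first gapped column of a gap costs ``gap_open`` (11), each
  further column ``gap_ext`` (1), i.e. a length-L gap costs 11 + (L-1).
* Traceback tie-break is "high road": diagonal > up (gap in subject, query
  residue consumed) > left (gap in query). Within a gap state, closing the
  gap (coming from the main matrix) is preferred over extending on ties.
* The best cell is the maximum of H; ties resolve to the smallest (i, j).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def sw_score_affine(a, b, sub, gap_open, gap_ext):
    """Optimal local alignment score, full Gotoh recurrences, linear memory."""
    n, m = a.shape[0], b.shape[0]
    H = np.zeros(m + 1, dtype=np.float64)
    F = np.full(m + 1, NEG, dtype=np.float64)
    best = 0.0
    for i in range(1, n + 1):
        diag = 0.0
        Hi_prev = 0.0
        E = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            E = max(Hi_prev - gap_open, E - gap_ext)
            F[j] = max(H[j] - gap_open, F[j] - gap_ext)
            h = diag + sub[ai, b[j - 1]]
            if F[j] > h:
                h = F[j]
            if E > h:
                h = E
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            Hi_prev = h
            if h > best:
                best = h
    return best


# traceback codes
_STOP = 0
_DIAG = 1
_UP = 2  # gap in b: consume a[i-1]
_LEFT = 3  # gap in a: consume b[j-1]


@njit(cache=True)
def sw_align(a, b, sub, gap_open, gap_ext):
    """Optimal local alignment with high-road traceback.

    Returns (score, qstart, qend, sstart, send, matches, mismatches,
    gaps_q, gaps_s) where gaps_q / gaps_s count alignment columns with a gap
    in a / in b respectively, and coordinates are 0-based half-open on a
    (query) and b (subject).
    """
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0.0:
        return (0.0, 0, 0, 0, 0, 0, 0, 0, 0)
    # traceback (priority: diagonal > up > left; gap close > gap extend)
    i, j = bi, bj
    matches = 0
    mismatches = 0
    gaps_q = 0
    gaps_s = 0
    while i > 0 and j > 0 and H[i, j] > 0.0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
            if a[i - 1] == b[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif h == F[i, j]:
            # run up the F gap until it closes
            while True:
                gaps_s += 1
                opened = H[i - 1, j] - gap_open == F[i, j]
                i -= 1
                if opened:
                    break
        else:
            while True:
                gaps_q += 1
                opened = H[i, j - 1] - gap_open == E[i, j]
                j -= 1
                if opened:
                    break
    return (best, i, bi, j, bj, matches, mismatches, gaps_q, gaps_s)


@njit(cache=True, inline="always")
def _lse3(x, y, z):
    m = x
    if y > m:
        m = y
    if z > m:
        m = z
    if m <= NEG:
        return NEG
    return m + math.log(math.exp(x - m) + math.exp(y - m) + math.exp(z - m))


@njit(cache=True)
def forward_bits(seq, lo_match, tMM, tMI, tMD, tIM, tII, tID, tDM, tDD, tDI):
    """Log-odds forward score of a sequence against a profile, in bits.

    ``seq``: residue indices (values >= 20 score as background, log-odds 0).
    ``lo_match``: (K+1, 21) natural-log odds match emissions, row j for M_j;
    column 20 is the out-of-alphabet residue (0.0). Transitions are natural
    logs; index j is the source column (M_0 is Begin, column K transitions
    lead to End via the *M-slot, e.g. tMM[K] = P(M_K -> End)).
    """
    L = seq.shape[0]
    K = lo_match.shape[0] - 1
    M = np.full((L + 1, K + 1), NEG, dtype=np.float64)
    I = np.full((L + 1, K + 1), NEG, dtype=np.float64)
    D = np.full((L + 1, K + 1), NEG, dtype=np.float64)
    M[0, 0] = 0.0  # Begin
    # row 0: deletions reachable without consuming residues
    for j in range(1, K + 1):
        frm_m = M[0, j - 1] + tMD[j - 1]
        frm_d = D[0, j - 1] + tDD[j - 1]
        frm_i = I[0, j - 1] + tID[j - 1]
        D[0, j] = _lse3(frm_m, frm_d, frm_i)
    for i in range(1, L + 1):
        x = seq[i - 1]
        if x > 20:
            x = 20
        # I_0 flank
        I[i, 0] = _lse3(M[i - 1, 0] + tMI[0], I[i - 1, 0] + tII[0], D[i - 1, 0] + tDI[0])
        for j in range(1, K + 1):
            M[i, j] = lo_match[j, x] + _lse3(
                M[i - 1, j - 1] + tMM[j - 1],
                I[i - 1, j - 1] + tIM[j - 1],
                D[i - 1, j - 1] + tDM[j - 1],
            )
            I[i, j] = _lse3(
                M[i - 1, j] + tMI[j], I[i - 1, j] + tII[j], D[i - 1, j] + tDI[j]
            )
            D[i, j] = _lse3(
                M[i, j - 1] + tMD[j - 1], D[i, j - 1] + tDD[j - 1], I[i, j - 1] + tID[j - 1]
            )
    total = _lse3(M[L, K] + tMM[K], I[L, K] + tIM[K], D[L, K] + tDM[K])
    return total / math.log(2.0)


@njit(cache=True)
def viterbi_match_columns(seq, lo_match, tMM, tMI, tMD, tIM, tII, tID, tDM, tDD, tDI):
    """Viterbi alignment of a sequence to the profile.

    Returns (col_res, span_start, span_end): ``col_res[j-1]`` is the 0-based
    sequence index emitted by match state M_j, or -1 for a deletion; the span
    covers residues consumed by match/insert states between M_1 and M_K.
    Ties prefer M > I > D at each step.
    """
    L = seq.shape[0]
    K = lo_match.shape[0] - 1
    M = np.full((L + 1, K + 1), NEG, dtype=np.float64)
    I = np.full((L + 1, K + 1), NEG, dtype=np.float64)
    D = np.full((L + 1, K + 1), NEG, dtype=np.float64)
    # backpointers: 0 = from M, 1 = from I, 2 = from D
    bM = np.zeros((L + 1, K + 1), dtype=np.int8)
    bI = np.zeros((L + 1, K + 1), dtype=np.int8)
    bD = np.zeros((L + 1, K + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, K + 1):
        cand_m = M[0, j - 1] + tMD[j - 1]
        cand_d = D[0, j - 1] + tDD[j - 1]
        cand_i = I[0, j - 1] + tID[j - 1]
        best = cand_m
        arg = 0
        if cand_i > best:
            best = cand_i
            arg = 1
        if cand_d > best:
            best = cand_d
            arg = 2
        D[0, j] = best
        bD[0, j] = arg
    for i in range(1, L + 1):
        x = seq[i - 1]
        if x > 20:
            x = 20
        cm = M[i - 1, 0] + tMI[0]
        ci = I[i - 1, 0] + tII[0]
        cd = D[i - 1, 0] + tDI[0]
        best = cm
        arg = 0
        if ci > best:
            best = ci
            arg = 1
        if cd > best:
            best = cd
            arg = 2
        I[i, 0] = best
        bI[i, 0] = arg
        for j in range(1, K + 1):
            cm = M[i - 1, j - 1] + tMM[j - 1]
            ci = I[i - 1, j - 1] + tIM[j - 1]
            cd = D[i - 1, j - 1] + tDM[j - 1]
            best = cm
            arg = 0
            if ci > best:
                best = ci
                arg = 1
            if cd > best:
                best = cd
                arg = 2
            M[i, j] = lo_match[j, x] + best
            bM[i, j] = arg
            cm = M[i - 1, j] + tMI[j]
            ci = I[i - 1, j] + tII[j]
            cd = D[i - 1, j] + tDI[j]
            best = cm
            arg = 0
            if ci > best:
                best = ci
                arg = 1
            if cd > best:
                best = cd
                arg = 2
            I[i, j] = best
            bI[i, j] = arg
            cm = M[i, j - 1] + tMD[j - 1]
            cd = D[i, j - 1] + tDD[j - 1]
            ci = I[i, j - 1] + tID[j - 1]
            best = cm
            arg = 0
            if ci > best:
                best = ci
                arg = 1
            if cd > best:
                best = cd
                arg = 2
            D[i, j] = best
            bD[i, j] = arg
    cm = M[L, K] + tMM[K]
    ci = I[L, K] + tIM[K]
    cd = D[L, K] + tDM[K]
    state = 0
    if ci > cm and ci >= cd:
        state = 1
    elif cd > cm and cd > ci:
        state = 2
    col_res = np.full(K, -1, dtype=np.int64)
    i, j = L, K
    span_start = L
    span_end = 0
    while not (state == 0 and j == 0):
        if state == 0:  # M_j emitted seq[i-1]
            col_res[j - 1] = i - 1
            if i - 1 < span_start:
                span_start = i - 1
            if i > span_end:
                span_end = i
            prev = bM[i, j]
            i -= 1
            j -= 1
            state = prev
        elif state == 1:  # I_j emitted seq[i-1]
            if 0 < j < K:
                if i - 1 < span_start:
                    span_start = i - 1
                if i > span_end:
                    span_end = i
            prev = bI[i, j]
            i -= 1
            state = prev
        else:  # D_j silent
            prev = bD[i, j]
            j -= 1
            state = prev
    if span_end == 0:
        span_start = 0
    return col_res, span_start, span_end
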
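"""Independent brute-force oracles used by the test suite.

These are written against the documented conventions of the package but
share no code with it: plain-Python dynamic programming for local alignment,
exhaustive state-path enumeration for the profile HMM, and a naive
union-find for connected components.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# local alignment (Gotoh with high-road traceback, gap = open + (L-1)*ext)


def sw_oracle(a: str, b: str, sub, gap_open: float = 11.0, gap_ext: float = 1.0):
    """Optimal local alignment statistics.

    Returns (score, matches, columns, qspan, sspan) for the optimal local
    alignment under the package's documented tie-breaks: best cell is the
    smallest (i, j) maximum; traceback prefers diagonal > up (consume a) >
    left (consume b); gap close preferred over gap extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_ext)
            s = sub(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0.0:
        return 0.0, 0, 0, (0, 0), (0, 0)
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0.0:
        s = sub(a[i - 1], b[j - 1])
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += 1 if a[i - 1] == b[j - 1] else 0
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == F[i][j]:
            while True:
                columns += 1
                opened = H[i - 1][j] - gap_open == F[i][j]
                i -= 1
                if opened:
                    break
        else:
            while True:
                columns += 1
                opened = H[i][j - 1] - gap_open == E[i][j]
                j -= 1
                if opened:
                    break
    return best, matches, columns, (i, bi), (j, bj)


# ---------------------------------------------------------------------------
# profile HMM forward by exhaustive path enumeration


def forward_oracle_bits(profile, protein: str) -> float:
    """Sum of P(path, seq)/P(seq | background) over ALL state paths of a
    fitted ProfileHMM, by explicit depth-first enumeration. Exponential in
    profile length and sequence length: use only on tiny instances."""
    K = profile.n_match_
    trans = profile.transitions_
    emis = profile.match_emissions_
    bg = profile.background
    aa_order = "ACDEFGHIKLMNPQRSTVWY"
    idx = {c: i for i, c in enumerate(aa_order)}
    L = len(protein)
    total = 0.0

    def walk(state: str, j: int, pos: int, odds: float) -> None:
        nonlocal total
        # transition to End is the M-slot out of column K
        if j == K:
            p_end = trans[state + "M"][K]
            if pos == L and p_end > 0:
                total += odds * p_end
        for nxt in ("M", "I", "D"):
            p = trans[state + nxt][j]
            if p <= 0.0:
                continue
            if nxt == "M":
                if j + 1 > K or pos >= L:
                    continue
                x = idx.get(protein[pos])
                e_odds = emis[j + 1][x] / bg[x] if x is not None else 1.0
                walk("M", j + 1, pos + 1, odds * p * e_odds)
            elif nxt == "I":
                if pos >= L:
                    continue
                walk("I", j, pos + 1, odds * p)  # insert emits background
            else:
                if j + 1 > K:
                    continue
                walk("D", j + 1, pos, odds * p)

    walk("M", 0, 0, 1.0)  # Begin behaves as M_0
    return math.log2(total)


# ---------------------------------------------------------------------------
# connected components by naive union-find


def components_oracle(nodes, edges):
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            v = parent[v]
        return v

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return sorted(map(frozenset, groups.values()), key=min)


# ---------------------------------------------------------------------------
# smallest string period


def smallest_period_oracle(s: str) -> int:
    for p in range(1, len(s) + 1):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)
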
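"""Independent reference implementations used only to check the package.

These deliberately share no code with mqfpcr: full dynamic-programming
alignment (Gotoh affine-gap, global and local), an exhaustive
concordant-pair AUC, and a brute-force binding-site scan.

Scoring convention matches the package: a gap of length L costs
open + L * extend (default 5 + 2L).
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def gotoh_global_score(a: str, b: str, match=1.0, mismatch=-2.0, gap_open=5.0, gap_ext=2.0) -> float:
    """Optimal global affine-gap alignment score by full DP (no heuristics)."""
    m, n = len(a), len(b)
    first = gap_open + gap_ext  # cost of a length-1 gap
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)  # gap in a (consumes b)
    F = np.full((m + 1, n + 1), NEG)  # gap in b (consumes a)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = max(H[0, j - 1] - first, E[0, j - 1] - gap_ext)
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = max(H[i - 1, 0] - first, F[i - 1, 0] - gap_ext)
        H[i, 0] = F[i, 0]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - first, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - first, F[i - 1, j] - gap_ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, E[i, j], F[i, j])
    return float(H[m, n])


try:
    from numba import njit

    @njit(cache=False)
    def _local_dp(av, bv, match, mismatch, first, ext):
        m, n = av.size, bv.size
        H = np.zeros((m + 1, n + 1))
        E = np.full((m + 1, n + 1), NEG)
        F = np.full((m + 1, n + 1), NEG)
        best = 0.0
        bi = 0
        bj = 0
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                e = H[i, j - 1] - first
                if E[i, j - 1] - ext > e:
                    e = E[i, j - 1] - ext
                E[i, j] = e
                f = H[i - 1, j] - first
                if F[i - 1, j] - ext > f:
                    f = F[i - 1, j] - ext
                F[i, j] = f
                s = match if av[i - 1] == bv[j - 1] else mismatch
                h = H[i - 1, j - 1] + s
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0.0:
                    h = 0.0
                H[i, j] = h
                if h > best:
                    best = h
                    bi = i
                    bj = j
        return best, bi, bj

except ImportError:  # pragma: no cover - numba is expected to be present
    def _local_dp(av, bv, match, mismatch, first, ext):
        m, n = av.size, bv.size
        H = np.zeros((m + 1, n + 1))
        E = np.full((m + 1, n + 1), NEG)
        F = np.full((m + 1, n + 1), NEG)
        best, bi, bj = 0.0, 0, 0
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                E[i, j] = max(H[i, j - 1] - first, E[i, j - 1] - ext)
                F[i, j] = max(H[i - 1, j] - first, F[i - 1, j] - ext)
                s = match if av[i - 1] == bv[j - 1] else mismatch
                h = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
                H[i, j] = h
                if h > best:
                    best, bi, bj = h, i, j
        return best, bi, bj


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def smith_waterman(a: str, b: str, match=1.0, mismatch=-2.0, gap_open=5.0, gap_ext=2.0):
    """Optimal local alignment: (score, a_start, a_end, b_start, b_end),
    0-based half-open coordinates.  Start found by a reverse DP pass."""
    first = gap_open + gap_ext
    av, bv = _encode(a), _encode(b)
    score, ae, be = _local_dp(av, bv, match, mismatch, first, gap_ext)
    # reverse pass on the prefixes ending at the optimum locates the start
    score2, ra, rb = _local_dp(av[:ae][::-1].copy(), bv[:be][::-1].copy(),
                               match, mismatch, first, gap_ext)
    assert abs(score - score2) < 1e-9
    return score, ae - ra, ae, be - rb, be


def concordant_pair_auc(pos, neg) -> float:
    """AUC as the concordant-pair fraction (ties credit 0.5)."""
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def brute_force_sites(core_expansions: list[str], template: str) -> list[tuple[int, str]]:
    """All exact occurrences of any expansion on either strand:
    (0-based position, strand)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    hits = []
    for strand in "+-":
        for exp in core_expansions:
            pat = exp if strand == "+" else "".join(comp[c] for c in reversed(exp))
            start = 0
            while True:
                i = template.find(pat, start)
                if i < 0:
                    break
                hits.append((i, strand))
                start = i + 1
    return sorted(set(hits))
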
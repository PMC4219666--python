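"""Independent brute-force oracles used to verify the core algorithms.

These deliberately use different decompositions from the implementations:
the folding oracle recurses on whether the *first* base pairs (the engine
recurses on the last), the count-test oracle sums the mass function in
plain floating point (the engine works in log space), and the duplex oracle
enumerates alignment paths recursively without memoisation (the engine is a
banded DP).
"""

from __future__ import annotations

import functools
import math

PAIR_E = {
    ("G", "C"): -3, ("C", "G"): -3,
    ("A", "T"): -2, ("T", "A"): -2,
    ("G", "T"): -1, ("T", "G"): -1,
}


def fold_oracle(seq: str, min_loop: int = 3) -> float:
    """Minimum energy by recursion on the first base: unpaired, or paired
    with every admissible k."""

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        e = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            pe = PAIR_E.get((seq[i], seq[k]))
            if pe is not None:
                e = min(e, pe + best(i + 1, k - 1) + best(k + 1, j))
        return e

    return float(best(0, len(seq) - 1))


def ac_pvalue_oracle(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided Audic-Claverie p by direct float summation of
    P(Y=y'|x) = r^y' (x+y')! / (x! y'! (1+r)^(x+y'+1)), r = N2/N1."""
    r = N2 / N1
    # P(0) = (1+r)^-(x+1); ratio P(y'+1)/P(y') = r (x+y'+1) / ((y'+1)(1+r))
    p = (1.0 + r) ** (-(x + 1))
    lower = 0.0
    upper = 0.0
    yv = 0
    mode = (x + 1) * r  # terms decay geometrically beyond here
    while True:
        if yv <= y:
            lower += p
        if yv >= y:
            upper += p
        if yv > y and yv > mode and p < upper * 1e-18:
            break
        p *= r * (x + yv + 1) / ((yv + 1) * (1.0 + r))
        yv += 1
    return min(1.0, 2.0 * min(lower, upper))


_PEN = {}
for _a, _b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PEN[(_a, _b)] = 0.0
for _a, _b in (("G", "T"), ("T", "G")):
    _PEN[(_a, _b)] = 0.5


def duplex_oracle(mirna: str, site: str, gap_penalty: float = 2.0,
                  max_gaps: int = 2) -> float:
    """Minimum total penalty over all global alignments with <= max_gaps,
    by plain recursion over alignment paths (no memoisation)."""
    a = mirna.upper().replace("U", "T")
    b = site.upper().replace("U", "T")[::-1]

    def rec(i: int, j: int, gaps: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = math.inf
        if i < len(a) and j < len(b):
            pen = _PEN.get((a[i], b[j]), 1.0)
            best = min(best, pen + rec(i + 1, j + 1, gaps))
        if gaps < max_gaps:
            if i < len(a):
                best = min(best, gap_penalty + rec(i + 1, j, gaps + 1))
            if j < len(b):
                best = min(best, gap_penalty + rec(i, j + 1, gaps + 1))
        return best

    return rec(0, 0, 0)
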
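"""Minimum-free-energy RNA secondary structure by base-pair dynamic programming.

A Nussinov-style model: each admitted pair contributes a fixed stabilising
energy (G:C -3, A:U -2, G:U -1, in kcal/mol-like units), hairpin loops must
hold at least 3 unpaired bases, and pseudoknots are excluded.  The optimum
is found by exact dynamic programming with a deterministic traceback, so the
folder is fully self-contained and verifiable against exhaustive enumeration
at small lengths.  This is deliberately not a nearest-neighbour stacking
model: the pipeline needs a reproducible, oracle-checkable stability score
for hairpin screening, not thermodynamic accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from srnapipe._seq import validate_alphabet

#: Pair energies (kcal/mol-like); anything absent cannot pair.
PAIR_ENERGY = {
    ("G", "C"): -3, ("C", "G"): -3,
    ("A", "T"): -2, ("T", "A"): -2,
    ("G", "T"): -1, ("T", "G"): -1,
}

MIN_LOOP = 3          # unpaired bases required inside a hairpin loop
MAX_FOLD_LENGTH = 400
_INF = 10 ** 6        # integer sentinel; all finite energies are small ints


@dataclass
class FoldResult:
    sequence: str                 # as given (U preserved)
    structure: str                # dot-bracket
    energy: float                 # kcal/mol, <= 0; 0 iff no pairs
    pairs: list[tuple[int, int]]

    def partner(self) -> list[int]:
        """Partner index per position (-1 if unpaired)."""
        p = [-1] * len(self.sequence)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p


def _pair_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    e = np.full((n, n), _INF, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            v = PAIR_ENERGY.get((seq[i], seq[j]))
            if v is not None:
                e[i, j] = v
    return e


def fold_mfe(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Optimal fold of ``sequence`` under the base-pair energy model.

    Recurrence over subsequence [i, j]: either j is unpaired, or j pairs
    with some k (k < j - min_loop), splitting the problem into [i, k-1] and
    [k+1, j-1].  Integer energies make the traceback comparisons exact.
    """
    if not 1 <= len(sequence) <= MAX_FOLD_LENGTH:
        raise ValueError(f"sequence length must be 1-{MAX_FOLD_LENGTH}")
    seq = validate_alphabet(sequence, context="fold input")
    n = len(seq)
    if n < min_loop + 2:
        return FoldResult(sequence, "." * n, 0.0, [])

    E = _pair_matrix(seq)
    M = np.zeros((n, n), dtype=np.int64)
    # strictly-lower-triangular entries of M stay 0, which doubles as the
    # empty-interval value M[i, i-1] in the recurrences below
    lower_inf = np.where(np.tri(n, k=-1, dtype=bool), _INF, 0)
    for j in range(min_loop + 1, n):
        hi = j - min_loop  # exclusive upper bound for the pairing partner k
        # b[k] = e(k, j) + M[k+1, j-1]; D[i, k] = M[i, k-1]
        b = E[:hi, j] + M[1 : hi + 1, j - 1]
        D = np.empty((hi, hi), dtype=np.int64)
        D[:, 0] = 0
        D[:, 1:] = M[:hi, : hi - 1]
        cand = D + b[None, :] + lower_inf[:hi, :hi]
        M[:hi, j] = np.minimum(M[:hi, j - 1], cand.min(axis=1))

    # deterministic traceback: prefer "j unpaired", then smallest pairing k
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if E[k, j] >= _INF:
                continue
            lk = M[i, k - 1] if k > i else 0
            if lk + M[k + 1, j - 1] + E[k, j] == M[i, j]:
                pairs.append((k, j))
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break

    struct = ["."] * n
    for i, j in pairs:
        struct[i], struct[j] = "(", ")"
    return FoldResult(sequence, "".join(struct), float(M[0, n - 1]), sorted(pairs))


def energy_of_structure(sequence: str, structure: str, min_loop: int = MIN_LOOP) -> float:
    """Score an explicit dot-bracket structure under the same energy model.

    Raises ValueError on unbalanced brackets, non-pairable partners or
    loops tighter than ``min_loop``.
    """
    seq = validate_alphabet(sequence, context="fold input")
    if len(structure) != len(seq):
        raise ValueError("structure/sequence length mismatch")
    stack: list[int] = []
    total = 0
    for j, c in enumerate(structure):
        if c == "(":
            stack.append(j)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            i = stack.pop()
            if j - i - 1 < min_loop:
                raise ValueError(f"loop shorter than {min_loop} at pair ({i},{j})")
            e = PAIR_ENERGY.get((seq[i], seq[j]))
            if e is None:
                raise ValueError(f"non-pairable bases {seq[i]}:{seq[j]} at ({i},{j})")
            total += e
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return float(total)
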
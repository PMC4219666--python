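"""miRNA target prediction by complementarity penalty scoring.

A miRNA is aligned 5'->3' against the reverse-complement orientation of a
candidate transcript site, under the psRNATarget-style penalty scheme:
Watson-Crick match 0, G:U wobble 0.5, mismatch 1, gap 2 (at most 2 gaps).
The total penalty of the optimal global alignment is the site score;
sites score <= 3.5 (equivalently "less than four", since scores move in
0.5 steps) are reported as targets.

``scan_transcript`` scores every window of the permitted lengths
(|miRNA| +/- 2 nt) with an exact vectorised banded DP, merges overlapping
hits keeping the lowest score, and recovers the duplex alignment for each
reported hit.  Seed-region penalty weighting is deliberately off: only the
total score gates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from srnapipe._seq import validate_alphabet
from srnapipe.diffexpr import DifferentialCall

GAP_PENALTY = 2.0
MAX_GAPS = 2
DEFAULT_CUTOFF = 3.5

_CODE = {c: i for i, c in enumerate("ACGT")}
_INF = 10 ** 6

# doubled integer penalties indexed [mirna base, target base in duplex]:
# complementary 0, G:U wobble 1 (=0.5), mismatch 2 (=1)
_PEN2 = np.full((4, 4), 2, dtype=np.int32)
for _a, _b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PEN2[_CODE[_a], _CODE[_b]] = 0
for _a, _b in (("G", "T"), ("T", "G")):
    _PEN2[_CODE[_a], _CODE[_b]] = 1


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int
    end: int
    score: float
    aln_mirna: str   # miRNA 5'->3'
    aln_match: str   # '|' match, 'o' wobble, ' ' otherwise
    aln_site: str    # site 3'->5'


def _codes(seq: str, context: str) -> np.ndarray:
    s = validate_alphabet(seq, context=context)
    return np.fromiter((_CODE[c] for c in s), dtype=np.int64, count=len(s))


def score_duplex(
    mirna: str,
    site: str,
    gap_penalty: float = GAP_PENALTY,
    max_gaps: int = MAX_GAPS,
) -> tuple[float, tuple[str, str, str]]:
    """Optimal duplex penalty of a miRNA against one site, with alignment.

    The site is taken in transcript orientation; internally it is reversed
    so column j of the alignment is the target base opposite miRNA base j.
    Ties in the traceback prefer match, then wobble, then mismatch, then gap.
    """
    a = _codes(mirna, "mirna")
    if not len(a) or not len(site):
        raise ValueError("empty sequence")
    b = _codes(site, "site")[::-1]
    if abs(len(a) - len(b)) > max_gaps:
        raise ValueError("site length must be within the gap allowance of the miRNA length")
    m, n = len(a), len(b)
    g2 = int(round(gap_penalty * 2))

    D = np.full((max_gaps + 1, m + 1, n + 1), _INF, dtype=np.int64)
    for g in range(max_gaps + 1):
        for j in range(min(g, n) + 1):
            D[g, 0, j] = g2 * j
        for i in range(min(g, m) + 1):
            D[g, i, 0] = g2 * i
    for g in range(max_gaps + 1):
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                best = D[g, i - 1, j - 1] + _PEN2[a[i - 1], b[j - 1]]
                if g > 0:
                    best = min(best, D[g - 1, i - 1, j] + g2, D[g - 1, i, j - 1] + g2)
                D[g, i, j] = best

    score2 = int(D[:, m, n].min())

    # traceback from the smallest gap count achieving the optimum
    g = int(np.argmin(D[:, m, n]))
    i, j = m, n
    am, al, asite = [], [], []
    sym = {0: "|", 1: "o", 2: " "}
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            pen = _PEN2[a[i - 1], b[j - 1]]
            if D[g, i, j] == D[g, i - 1, j - 1] + pen:
                am.append(mirna[i - 1].upper())
                asite.append(site[len(site) - j].upper())
                al.append(sym[int(pen)])
                i, j = i - 1, j - 1
                continue
        if g > 0 and i > 0 and D[g, i, j] == D[g - 1, i - 1, j] + g2:
            am.append(mirna[i - 1].upper())
            asite.append("-")
            al.append(" ")
            i, g = i - 1, g - 1
            continue
        am.append("-")
        asite.append(site[len(site) - j].upper())
        al.append(" ")
        j, g = j - 1, g - 1
    aln = ("".join(reversed(am)), "".join(reversed(al)), "".join(reversed(asite)))
    return score2 / 2.0, aln


def _scan_scores_impl(a: np.ndarray, t: np.ndarray, L: int,
                      g2: int, max_gaps: int) -> np.ndarray:
    """Exact duplex scores (doubled ints) of every length-L window of t."""
    m = len(a)
    W = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    nw = W.shape[0]
    D = np.full((max_gaps + 1, nw, L + 1), _INF, dtype=np.int32)
    for g in range(max_gaps + 1):
        for j in range(min(g, L) + 1):
            D[g, :, j] = g2 * j
    for i in range(1, m + 1):
        pen = _PEN2[a[i - 1], W]            # (nw, L)
        new = np.full_like(D, _INF)
        for g in range(max_gaps + 1):
            new[g, :, 0] = g2 * i if i <= g else _INF
            diag = D[g, :, :-1] + pen
            if g > 0:
                gap_i = D[g - 1, :, 1:] + g2         # miRNA base vs gap
                gap_j = new[g - 1, :, :-1] + g2      # gap vs target base
                new[g, :, 1:] = np.minimum(diag, np.minimum(gap_i, gap_j))
            else:
                new[g, :, 1:] = diag
        D = new
    return D[:, :, L].min(axis=0)


def scan_transcript(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    cutoff: float = DEFAULT_CUTOFF,
    gap_penalty: float = GAP_PENALTY,
    max_gaps: int = MAX_GAPS,
) -> list[TargetHit]:
    """All target sites of one miRNA on one transcript at the score cutoff.

    Every window of length |miRNA| +/- max_gaps is scored exactly;
    overlapping hits are merged keeping the lowest score; hits are sorted
    by score then position.  A transcript shorter than the miRNA yields an
    empty list.
    """
    a = _codes(mirna, "mirna")
    if len(transcript) < len(a):
        return []
    t = _codes(transcript, "transcript")
    g2 = int(round(gap_penalty * 2))
    cut2 = int(round(cutoff * 2))

    raw: list[tuple[float, int, int]] = []
    for L in range(len(a) - max_gaps, len(a) + max_gaps + 1):
        if L < 1 or L > len(t):
            continue
        scores = _scan_scores_impl(a, t, L, g2, max_gaps)
        for s in np.nonzero(scores <= cut2)[0]:
            raw.append((scores[s] / 2.0, int(s), int(s) + L))

    # merge overlaps, keeping the lowest score (ties: earliest, shortest)
    raw.sort(key=lambda h: (h[0], h[1], h[2]))
    kept: list[tuple[float, int, int]] = []
    for sc, s, e in raw:
        if all(e <= ks or s >= ke for _, ks, ke in kept):
            kept.append((sc, s, e))
    hits = []
    for sc, s, e in sorted(kept, key=lambda h: (h[0], h[1])):
        score, aln = score_duplex(mirna, transcript[s:e], gap_penalty, max_gaps)
        hits.append(TargetHit(mirna_id, transcript_id, s, e, score, *aln))
    return hits


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[TargetHit]:
    """Scan every miRNA against every transcript."""
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            hits.extend(scan_transcript(mid, mirnas[mid], tid, transcripts[tid], cutoff))
    return hits


def hits_frame(hits: Sequence[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.mirna_id, h.transcript_id, h.start, h.end, h.score,
             h.aln_mirna, h.aln_match, h.aln_site)
            for h in hits
        ],
        columns=["mirna_id", "transcript_id", "start", "end", "score",
                 "aln_mirna", "aln_match", "aln_site"],
    )


def concordance_report(
    de_calls: Iterable[DifferentialCall],
    hits: Iterable[TargetHit],
    target_log2fc: Mapping[str, float],
    flat_threshold: float = 1.0,
) -> pd.DataFrame:
    """Sign relation between each DE miRNA and its predicted targets.

    Labels: same / opposite by log2FC sign, flat when either |log2FC| falls
    below the threshold, missing when the target has no expression entry.
    """
    mirna_lfc = {c.mirna_id: c.log2fc for c in de_calls}
    rows = []
    for h in hits:
        if h.mirna_id not in mirna_lfc:
            continue
        mlfc = mirna_lfc[h.mirna_id]
        if h.transcript_id not in target_log2fc:
            rows.append((h.mirna_id, h.transcript_id, mlfc, math.nan, "missing"))
            continue
        tlfc = target_log2fc[h.transcript_id]
        if abs(mlfc) < flat_threshold or abs(tlfc) < flat_threshold:
            rel = "flat"
        elif (mlfc > 0) == (tlfc > 0):
            rel = "same"
        else:
            rel = "opposite"
        rows.append((h.mirna_id, h.transcript_id, mlfc, tlfc, rel))
    return pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "mirna_log2fc",
                       "target_log2fc", "relation"],
    )
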
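"""Novel miRNA discovery: precursor excision, folding and hairpin screening.

Unclassified tags that map perfectly to transcript contigs are treated as
putative mature miRNAs.  Around each perfect hit two candidate precursor
windows are excised (the tag as the 5p arm: 20 nt upstream + 160 nt
downstream; as the 3p arm: the mirror), on both strands.  Each window is
folded with the package's MFE engine and screened with MIREAP-style
criteria: mature length 18-26 nt, folding energy <= -18 kcal/mol, the
mature entirely on one stem arm (no terminal-loop overlap), at least 14 of
its bases paired, and no asymmetric bulge larger than 4 nt inside the
mature duplex.  Rejections carry the first failed criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from srnapipe._seq import revcomp
from srnapipe.fold import FoldResult, fold_mfe
from srnapipe.preprocess import SmallRNATag


@dataclass
class HairpinCriteria:
    min_mature_len: int = 18
    max_mature_len: int = 26
    max_energy: float = -18.0        # kcal/mol
    max_loop_fraction: float = 0.0   # strict: no mature base in the terminal loop
    min_paired: int = 14
    max_bulge: int = 4


@dataclass
class PrecursorWindow:
    """One excised candidate precursor around a perfect tag hit."""

    sequence: str
    start: int            # on the stranded contig sequence, 0-based half-open
    end: int
    strand: str
    arm_hypothesis: str   # which arm the tag is assumed to occupy
    mature_start: int     # tag span within the window
    mature_end: int
    clipped: bool


@dataclass
class HairpinCandidate:
    candidate_id: str
    mature: str
    arm: str
    strand: str
    length: int
    precursor: str
    start: int
    end: int
    contig_id: str
    fold: FoldResult
    verdict: str
    total_reads: int = 0
    mature_start: int = 0
    mature_end: int = 0


def excise_precursors(
    tag: str,
    contig: str,
    upstream: int = 20,
    downstream: int = 160,
) -> list[PrecursorWindow]:
    """Candidate precursor windows around every perfect hit of ``tag``.

    Both strands are searched; minus-strand windows are computed on the
    reverse complement of the contig and their coordinates refer to that
    reverse-complemented sequence.  Windows are clipped at contig ends and
    flagged.  No perfect hit yields an empty list.
    """
    out: list[PrecursorWindow] = []
    for strand, seq in (("+", contig), ("-", revcomp(contig))):
        pos = seq.find(tag)
        while pos != -1:
            s, e = pos, pos + len(tag)
            for arm, lo, hi in (("5p", s - upstream, e + downstream),
                                ("3p", s - downstream, e + upstream)):
                clo, chi = max(0, lo), min(len(seq), hi)
                out.append(PrecursorWindow(
                    sequence=seq[clo:chi], start=clo, end=chi, strand=strand,
                    arm_hypothesis=arm, mature_start=s - clo, mature_end=e - clo,
                    clipped=(clo != lo or chi != hi),
                ))
            pos = seq.find(tag, pos + 1)
    return out


def _terminal_loops(partner: list[int]) -> list[tuple[int, int]]:
    """Spans (open, close) of hairpin loops: pairs with no pair inside."""
    loops = []
    for i, j in enumerate(partner):
        if j > i and all(partner[k] == -1 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def evaluate_hairpin(
    precursor: str,
    mature_span: tuple[int, int],
    criteria: HairpinCriteria | None = None,
    *,
    strand: str = "+",
    contig_id: str = "",
    window_start: int = 0,
) -> HairpinCandidate:
    """Fold a precursor and apply the acceptance criteria to its mature span.

    The reject reason is the first failed criterion, checked in the order
    length, energy, loop_overlap, pairing, bulge.
    """
    criteria = criteria or HairpinCriteria()
    ms, me = mature_span
    if not (0 <= ms < me <= len(precursor)):
        raise ValueError(f"mature span {mature_span} outside precursor (len {len(precursor)})")
    mature = precursor[ms:me]
    fr = fold_mfe(precursor)
    partner = fr.partner()

    verdict = "accept"
    n_mature = me - ms
    if not criteria.min_mature_len <= n_mature <= criteria.max_mature_len:
        verdict = "reject:length"
    elif fr.energy > criteria.max_energy:
        verdict = "reject:energy"
    else:
        # terminal-loop overlap and single-arm placement
        loops = _terminal_loops(partner)
        in_loop = sum(
            1 for i in range(ms, me)
            if any(lo < i < hi for lo, hi in loops)
        )
        partners = [partner[i] for i in range(ms, me) if partner[i] != -1]
        left = sum(1 for p in partners if p < ms)
        right = sum(1 for p in partners if p >= me)
        if in_loop > criteria.max_loop_fraction * n_mature or (left and right):
            verdict = "reject:loop_overlap"
        elif len(partners) < criteria.min_paired:
            verdict = "reject:pairing"
        else:
            paired_pos = [i for i in range(ms, me) if partner[i] != -1]
            for a, b in zip(paired_pos, paired_pos[1:]):
                gap_m = b - a - 1
                gap_p = abs(partner[a] - partner[b]) - 1
                if abs(gap_m - gap_p) > criteria.max_bulge:
                    verdict = "reject:bulge"
                    break

    partners = [partner[i] for i in range(ms, me) if partner[i] != -1]
    arm = "5p" if (partners and partners[0] >= me) else "3p"
    return HairpinCandidate(
        candidate_id="", mature=mature, arm=arm, strand=strand,
        length=n_mature, precursor=precursor,
        start=window_start, end=window_start + len(precursor),
        contig_id=contig_id, fold=fr, verdict=verdict,
        mature_start=ms, mature_end=me,
    )


def name_candidates(accepted: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Assign lch-MIR-NN ids: descending total read count, ties by sequence."""
    ordered = sorted(accepted, key=lambda c: (-c.total_reads, c.mature))
    for i, c in enumerate(ordered, start=1):
        c.candidate_id = f"lch-MIR-{i:02d}"
    return ordered


def discover_novel(
    tags: Iterable[SmallRNATag],
    transcripts: Mapping[str, str],
    criteria: HairpinCriteria | None = None,
    max_candidate_tags: int = 50,
    upstream: int = 20,
    downstream: int = 160,
) -> list[HairpinCandidate]:
    """Full novel-miRNA search over a set of (unclassified) tags.

    The ``max_candidate_tags`` most abundant tags are mapped perfectly to
    the transcript contigs; each hit's precursor windows are folded and
    screened.  Per tag the best accepted candidate (lowest energy) is kept;
    accepted candidates are then named.
    """
    criteria = criteria or HairpinCriteria()
    ranked = sorted(tags, key=lambda t: (-t.total, t.sequence))[:max_candidate_tags]
    accepted: list[HairpinCandidate] = []
    for tag in ranked:
        best: HairpinCandidate | None = None
        for tid in sorted(transcripts):
            contig = transcripts[tid]
            if tag.sequence not in contig and tag.sequence not in revcomp(contig):
                continue
            for win in excise_precursors(tag.sequence, contig, upstream, downstream):
                cand = evaluate_hairpin(
                    win.sequence, (win.mature_start, win.mature_end), criteria,
                    strand=win.strand, contig_id=tid, window_start=win.start,
                )
                if cand.verdict != "accept":
                    continue
                cand.total_reads = tag.total
                if best is None or cand.fold.energy < best.fold.energy:
                    best = cand
        if best is not None:
            accepted.append(best)
    return name_candidates(accepted)


def candidates_frame(candidates: list[HairpinCandidate]) -> pd.DataFrame:
    """Report table mirroring the conventional novel-miRNA record columns."""
    return pd.DataFrame(
        [
            (c.candidate_id, c.mature, c.arm, c.strand, c.length, c.fold.energy,
             c.contig_id, c.start, c.end, c.verdict)
            for c in candidates
        ],
        columns=["Novel miRNA", "miRNA sequence", "3p/5p", "strand (+-)",
                 "length (nt)", "folding energy (kcal/mol)",
                 "contig", "start", "end", "verdict"],
    )
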
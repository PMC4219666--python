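"""Known-miRNA identification and per-library count matrices.

A clean tag is matched against each mature reference by a banded ungapped
alignment allowing end-offsets of up to +/-2 nt (isomiR shifts) and accepted
at identity >= 0.95 and coverage >= 0.90 of the tag.  Each accepted tag
contributes its full read counts to exactly one miRNA: its best hit by
identity, then coverage, then lexicographically smallest id, so the matrix
is invariant under permutation of the reference order.

Family labels are parsed from ids by stripping the species prefix, any arm
suffix and the trailing member letter (lch-miR396f-3p -> miR396).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from srnapipe.preprocess import SmallRNATag

_FAMILY_RE = re.compile(r"(?:^|-)((?:miR|MIR)[0-9]+)", re.IGNORECASE)


@dataclass
class MatchThresholds:
    min_identity: float = 0.95
    min_coverage: float = 0.90
    max_end_offset: int = 2


@dataclass
class MirnaCountRow:
    mirna_id: str
    family: str
    counts: dict[str, int] = field(default_factory=dict)
    tags: list[str] = field(default_factory=list)


def family_label(mirna_id: str) -> str:
    """miR-family label of an id: lch-miR156d -> miR156."""
    m = _FAMILY_RE.search(mirna_id)
    if not m:
        return mirna_id
    return "miR" + re.sub(r"^(miR|MIR)", "", m.group(1), flags=re.IGNORECASE)


def match_tag_to_mature(
    tag: str, mature: str, thresholds: MatchThresholds | None = None
) -> tuple[float, float, bool]:
    """Best banded ungapped alignment of a tag to one mature sequence.

    Returns (identity, coverage, accept); identity = matches / aligned
    columns, coverage = aligned columns / tag length, over start offsets
    within +/-max_end_offset.
    """
    thresholds = thresholds or MatchThresholds()
    if not tag or not mature:
        raise ValueError("empty sequence")
    if not (15 <= len(tag) <= 35 and 15 <= len(mature) <= 35):
        raise ValueError("sequences must be 15-35 nt")
    best = (0.0, 0.0)
    for offset in range(-thresholds.max_end_offset, thresholds.max_end_offset + 1):
        t0 = max(0, -offset)
        t1 = min(len(tag), len(mature) - offset)
        aligned = t1 - t0
        if aligned <= 0:
            continue
        matches = sum(1 for i in range(t0, t1) if tag[i] == mature[i + offset])
        ident = matches / aligned
        cov = aligned / len(tag)
        if (ident, cov) > best:
            best = (ident, cov)
    ident, cov = best
    accept = ident >= thresholds.min_identity and cov >= thresholds.min_coverage
    return ident, cov, accept


def build_count_matrix(
    tags: Iterable[SmallRNATag],
    mature_set: Mapping[str, str],
    thresholds: MatchThresholds | None = None,
) -> list[MirnaCountRow]:
    """Assign accepted tags to their single best mature hit and sum counts."""
    thresholds = thresholds or MatchThresholds()
    rows: dict[str, MirnaCountRow] = {}
    for tag in tags:
        best = None  # (-identity, -coverage, mirna_id)
        for mid in sorted(mature_set):
            ident, cov, ok = match_tag_to_mature(tag.sequence, mature_set[mid], thresholds)
            if ok:
                key = (-ident, -cov, mid)
                if best is None or key < best[0]:
                    best = (key, mid)
        if best is None:
            continue
        mid = best[1]
        row = rows.setdefault(mid, MirnaCountRow(mid, family_label(mid)))
        row.tags.append(tag.sequence)
        for lib, c in tag.counts.items():
            row.counts[lib] = row.counts.get(lib, 0) + c
    return sorted(rows.values(), key=lambda r: r.mirna_id)


def count_matrix_frame(rows: list[MirnaCountRow], libraries: list[str]) -> pd.DataFrame:
    """Tidy count matrix: one row per miRNA, one column per library."""
    data = [
        [r.mirna_id, r.family] + [r.counts.get(lib, 0) for lib in libraries]
        for r in rows
    ]
    return pd.DataFrame(data, columns=["mirna_id", "family"] + list(libraries))
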
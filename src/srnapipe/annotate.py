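"""Classification of clean tags against ncRNA and mature-miRNA references.

Tags are searched with a seeded ungapped aligner (exact 12-mer seed, extended
to the full tag) and accepted at >= 95% identity and >= 90% coverage by
default.  A tag hitting several categories is assigned by the fixed priority
rRNA > tRNA > snRNA > snoRNA > miRNA; everything else is "unclassified".

The identity+coverage gates replace the E-value cutoff a database search
would apply: without a database-size model an E-value is not meaningful
here, and the gates are the operative thresholds in any case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from srnapipe.preprocess import SmallRNATag
from srnapipe.simdata import ReferenceBundle

CATEGORY_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")
SEED_K = 12


@dataclass
class AnnotationThresholds:
    min_identity: float = 0.95
    min_coverage: float = 0.90


def _build_seed_index(refs: list[tuple[str, str, str]]) -> dict[str, list[tuple[int, int]]]:
    """kmer -> list of (reference index, position)."""
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, (_rid, seq, _cat) in enumerate(refs):
        for p in range(len(seq) - SEED_K + 1):
            index.setdefault(seq[p : p + SEED_K], []).append((ri, p))
    return index


def _extend(tag: str, ref: str, offset: int) -> tuple[float, float]:
    """Ungapped identity/coverage of ``tag`` anchored on ``ref`` at offset."""
    t0 = max(0, -offset)
    t1 = min(len(tag), len(ref) - offset)
    aligned = t1 - t0
    if aligned <= 0:
        return 0.0, 0.0
    matches = sum(1 for i in range(t0, t1) if tag[i] == ref[i + offset])
    return matches / aligned, aligned / len(tag)


def classify_tags(
    tags: Iterable[SmallRNATag],
    bundle: ReferenceBundle,
    thresholds: AnnotationThresholds | None = None,
) -> pd.DataFrame:
    """Assign each tag one category (or "unclassified") with hit statistics.

    Returns a frame indexed by tag sequence with columns category, ref_id,
    identity, coverage.  Classification depends only on the tag sequence, so
    duplicates and input order cannot change the result.
    """
    thresholds = thresholds or AnnotationThresholds()
    refs: list[tuple[str, str, str]] = []
    for nid, (seq, cat) in sorted(bundle.ncrnas.items()):
        refs.append((nid, seq, cat))
    for mid, seq in sorted(bundle.mature_mirnas.items()):
        refs.append((mid, seq, "miRNA"))
    index = _build_seed_index(refs)
    prio = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}

    rows = []
    for tag in tags:
        s = tag.sequence
        seen: set[tuple[int, int]] = set()
        best = None  # (priority, -identity, -coverage, ref_id)
        for p in range(max(0, len(s) - SEED_K + 1)):
            for ri, rp in index.get(s[p : p + SEED_K], ()):
                offset = rp - p
                if (ri, offset) in seen:
                    continue
                seen.add((ri, offset))
                rid, rseq, cat = refs[ri]
                ident, cov = _extend(s, rseq, offset)
                if ident >= thresholds.min_identity and cov >= thresholds.min_coverage:
                    key = (prio[cat], -ident, -cov, rid)
                    if best is None or key < best[0]:
                        best = (key, rid, cat, ident, cov)
        if best is None:
            rows.append((s, "unclassified", None, float("nan"), float("nan")))
        else:
            _, rid, cat, ident, cov = best
            rows.append((s, cat, rid, ident, cov))
    return pd.DataFrame(
        rows, columns=["sequence", "category", "ref_id", "identity", "coverage"]
    ).set_index("sequence")


def category_proportions(
    annotation: pd.DataFrame, tags: Iterable[SmallRNATag]
) -> pd.DataFrame:
    """Read-weighted per-library category proportions (sums to 1 per library)."""
    rows: dict[tuple[str, str], int] = {}
    for tag in tags:
        cat = annotation.loc[tag.sequence, "category"] if tag.sequence in annotation.index else "unclassified"
        for lib, c in tag.counts.items():
            rows[(lib, cat)] = rows.get((lib, cat), 0) + c
    if not rows:
        return pd.DataFrame(columns=["library", "category", "reads", "proportion"])
    df = pd.DataFrame(
        [(lib, cat, c) for (lib, cat), c in sorted(rows.items())],
        columns=["library", "category", "reads"],
    )
    df["proportion"] = df["reads"] / df.groupby("library")["reads"].transform("sum")
    return df
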
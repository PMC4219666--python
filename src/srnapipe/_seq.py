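"""Sequence helpers shared across modules.

All sequences are held internally in the DNA alphabet (T, not U); FASTA and
FASTQ are emitted in DNA form as well.  Folding and duplex scoring convert on
entry, so U and T are interchangeable at those surfaces.
"""

from __future__ import annotations

DNA = "ACGT"

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA (T) form."""
    return seq.upper().replace("U", "T")


def validate_alphabet(seq: str, *, allow_u: bool = True, context: str = "sequence") -> str:
    """Return the DNA-form sequence, raising ValueError on foreign characters."""
    s = seq.upper()
    if allow_u:
        s = s.replace("U", "T")
    bad = set(s) - set(DNA)
    if bad:
        raise ValueError(f"invalid character(s) {sorted(bad)} in {context}: {seq!r}")
    return s
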
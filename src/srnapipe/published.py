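"""Published summary tables from the *Leymus chinensis* stress sRNA study.

These are the printed read-accounting ledgers for the three sequencing
libraries (control, saline-alkali, drought) and the printed novel-miRNA
records (mature sequence, hairpin arm, strand, length, folding energy in
kcal/mol as reported by the original RNAfold evaluation).  They serve as
fixed inputs for ledger arithmetic and record-semantics checks; the pipeline
itself never depends on them.
"""

from __future__ import annotations

from srnapipe.preprocess import FilterLedger

#: Per-library read accounting as printed (reads, not unique tags).
PUBLISHED_LEDGERS: dict[str, FilterLedger] = {
    "control": FilterLedger(
        raw_reads=15_712_504,
        high_quality=15_301_799,
        adapter3_null=212_414,
        insert_null=4_465,
        adapter5_contaminant=148_528,
        shorter_than_18nt=108_118,
        polyA=2_567,
        clean_reads=14_825_707,
    ),
    "saline_alkali": FilterLedger(
        raw_reads=15_076_385,
        high_quality=14_644_590,
        adapter3_null=266_964,
        insert_null=2_686,
        adapter5_contaminant=21_684,
        shorter_than_18nt=162_419,
        polyA=626,
        clean_reads=14_190_211,
    ),
    "drought": FilterLedger(
        raw_reads=14_725_482,
        high_quality=14_332_735,
        adapter3_null=158_349,
        insert_null=6_507,
        adapter5_contaminant=153_276,
        shorter_than_18nt=155_359,
        polyA=3_108,
        clean_reads=13_856_136,
    ),
}

#: Printed clean/high-quality percentages, rounded to 2 decimals.
PUBLISHED_CLEAN_PCT = {"control": 96.89, "saline_alkali": 96.90, "drought": 96.67}

#: Novel miRNA records: id -> (mature sequence, arm, strand, length nt, MFE kcal/mol).
PUBLISHED_NOVEL_MIRNAS: dict[str, tuple[str, str, str, int, float]] = {
    "lch-MIR-01": ("TCTTATATTATTGGACGGAGG", "3p", "+", 21, -72.5),
    "lch-MIR-02": ("AAGTAATTTGAGACGGAGGGAGT", "3p", "+", 23, -58.35),
    "lch-MIR-03": ("AAAACATCAACAATCGGAACTTA", "5p", "-", 23, -31.03),
    "lch-MIR-04": ("GTGTGGCGGCATGGGGATGT", "3p", "+", 20, -42.1),
    "lch-MIR-05": ("TGAGAGTGCGAATACAAGGAGGT", "5p", "-", 23, -21.7),
    "lch-MIR-06": ("ATTTCTGGACGGAGGGAGTAT", "5p", "+", 21, -19.1),
    "lch-MIR-07": ("AAGAGTAGCGTTGATACACCGT", "5p", "-", 22, -68.0),
    "lch-MIR-08": ("AAGAATTATGGAATGGAGGGA", "3p", "-", 21, -56.3),
    "lch-MIR-09": ("AAGACAAGTAATTTGGGACGG", "3p", "+", 21, -45.5),
    "lch-MIR-10": ("CTCTTATTGAATCGCGGTAAAGT", "3p", "-", 23, -58.3),
    "lch-MIR-11": ("ATGTGTGTGTCTGTGTGTGTA", "5p", "-", 21, -110.7),
    "lch-MIR-12": ("TTCTTCGACTTGGCCATCTCCC", "5p", "+", 21, -61.3),
    "lch-MIR-13": ("AATAGGTAGGGATGACAGGATT", "5p", "+", 22, -42.5),
    "lch-MIR-14": ("GGGACGAGTTGGAAGAGGAAT", "3p", "+", 21, -22.5),
    "lch-MIR-15": ("AGGCTGTGGAGAGATGGCTGAGT", "3p", "-", 23, -26.4),
    "lch-MIR-16": ("TTTAGGAACGGAGGAAGTACA", "5p", "-", 21, -52.6),
}


def novel_mirna_lengths() -> dict[str, int]:
    """Length accessor on the published mature sequences (computed, not copied)."""
    return {mid: len(rec[0]) for mid, rec in PUBLISHED_NOVEL_MIRNAS.items()}
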
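"""Read cleaning, ledger accounting and length histograms."""

import pytest
from hypothesis import given, settings, strategies as st

from srnapipe.preprocess import (
    CleanParams,
    FilterLedger,
    clean_reads,
    ledger_accounting,
    length_distribution,
    merge_tag_tables,
    SmallRNATag,
)

A5 = "TCGTATGCCGTCTTCTGCTTG"
A3 = "GTTCAGAGTTCTACAGTCCGACGATC"
HQ = "I" * 80


def read(seq, qual=None, rid="r1"):
    return (rid, seq, (qual or HQ)[: len(seq)])


INSERT21 = "ACGTCATGCTAGCTAGCTGAT"


@pytest.mark.parametrize(
    "seq,qual,category",
    [
        # designed pass-through: adapter5 + 21-nt insert + adapter3
        (A5 + INSERT21 + A3, HQ, "clean"),
        # low quality dominates everything
        (A5 + INSERT21 + A3, "#" * 80, "low_quality"),
        # 3' adapter absent
        (A5 + INSERT21 + "CCCCCCCCCCCCCCCCCCCCCCCCCC", HQ, "adapter3_null"),
        # adapters ligated back-to-back: no insert
        (A5 + A3, HQ, "insert_null"),
        # 5' adapter 8-mer inside the insert
        (A5 + "ACGTC" + A5[:8] + "ATCGATCG" + A3, HQ, "adapter5_contaminant"),
        # insert below 18 nt
        (A5 + "ACGTCATGCTAG" + A3, HQ, "shorter_than_18nt"),
        # insert above the 30-nt window shares the length-filter bucket
        (A5 + "ACGTCATGCTAGCTAGCTGATCGATCGATCGT" + A3, HQ, "shorter_than_18nt"),
        # pure-A insert of valid length
        (A5 + "A" * 20 + A3, HQ, "polyA"),
    ],
)
def test_single_read_routing(seq, qual, category):
    """Each engineered read lands in exactly its designed ledger category."""
    tags, ledger = clean_reads([read(seq, qual)], A5, A3, library="lib")
    assert ledger.raw_reads == 1
    if category == "clean":
        assert ledger.clean_reads == 1 and tags[0].sequence == INSERT21
        assert tags[0].counts == {"lib": 1}
    elif category == "low_quality":
        assert ledger.high_quality == 0 and not tags
    else:
        assert getattr(ledger, category) == 1 and not tags
    acct = ledger_accounting(ledger)
    assert acct["verdict"] == "consistent"


def test_tag_collapsing_counts_duplicates():
    reads = [read(A5 + INSERT21 + A3, rid=f"r{i}") for i in range(5)]
    other = "TTGACATGCTAGCTAGCTGAC"
    reads.append(read(A5 + other + A3, rid="r9"))
    tags, ledger = clean_reads(reads, A5, A3, library="lib")
    assert ledger.clean_reads == 6
    assert {t.sequence: t.counts["lib"] for t in tags} == {INSERT21: 5, other: 1}
    # tag counts sum to ledger clean reads
    assert sum(t.counts["lib"] for t in tags) == ledger.clean_reads


def test_empty_input_gives_zero_ledger():
    tags, ledger = clean_reads([], A5, A3)
    assert not tags and ledger.raw_reads == 0
    acct = ledger_accounting(ledger)
    assert acct["clean_reads"] == 0 and not acct["percentage_defined"]
    assert acct["clean_pct"] == 0.0


def test_malformed_fastq_reports_record_index(tmp_path):
    p = tmp_path / "bad.fastq"
    p.write_text("@r1\nACGT\n+\nIIII\nBADLINE\nACGT\n+\nIIII\n")
    with pytest.raises(ValueError, match="index"):
        clean_reads(p, A5, A3)


def test_recleaning_clean_inserts_is_idempotent():
    """Inserts that already survived cleaning survive a second pass intact."""
    reads = [read(A5 + INSERT21 + A3)]
    tags1, _ = clean_reads(reads, A5, A3, library="lib")
    reads2 = [read(A5 + t.sequence + A3, rid=f"x{i}") for i, t in enumerate(tags1)]
    tags2, _ = clean_reads(reads2, A5, A3, library="lib")
    assert {t.sequence for t in tags2} == {t.sequence for t in tags1}


def test_ledger_accounting_rejects_negative_fields():
    with pytest.raises(ValueError, match="negative"):
        ledger_accounting(FilterLedger(raw_reads=10, high_quality=5, polyA=-1))


def test_length_distribution_forced_arithmetic():
    tags = [
        SmallRNATag("A" * 10 + "CGTCATGCTG", {"lib": 30}),          # 20 nt
        SmallRNATag("ACGTACGTACGTACGTACGTACGT", {"lib": 70}),       # 24 nt
    ]
    df = length_distribution(tags)
    by_len = df.set_index("length")["proportion"]
    assert by_len[20] == pytest.approx(0.30)
    assert by_len[24] == pytest.approx(0.70)
    assert df.empty is False
    assert length_distribution([]).empty


def test_merge_tag_tables_sums_per_library():
    t1 = [SmallRNATag(INSERT21, {"a": 7})]
    t2 = [SmallRNATag(INSERT21, {"b": 3})]
    merged = merge_tag_tables({"a": t1, "b": t2})
    assert merged[0].counts == {"a": 7, "b": 3}
    assert merged[0].total == 10


@st.composite
def arbitrary_reads(draw):
    n = draw(st.integers(0, 30))
    reads = []
    for i in range(n):
        kind = draw(st.integers(0, 5))
        body = draw(st.text(alphabet="ACGT", min_size=1, max_size=45))
        if kind == 0:
            seq = A5 + body + A3
        elif kind == 1:
            seq = A5 + body
        elif kind == 2:
            seq = body + A3
        elif kind == 3:
            seq = body
        elif kind == 4:
            seq = A5 + "A" * draw(st.integers(1, 30)) + A3
        else:
            seq = A5 + A3
        seq = seq[: draw(st.integers(1, len(seq)))]
        qual = ("#" if draw(st.booleans()) else "I") * len(seq)
        reads.append((f"r{i}", seq, qual))
    return reads


@given(arbitrary_reads())
@settings(max_examples=60, deadline=None)
def test_ledger_conservation_on_arbitrary_reads(reads):
    """clean = high_quality - sum(removals) on any input, and tag counts
    always sum to the clean-read total."""
    tags, ledger = clean_reads(reads, A5, A3, library="lib")
    assert ledger.raw_reads == len(reads)
    assert ledger.clean_reads == ledger.high_quality - ledger.removals()
    assert sum(t.counts["lib"] for t in tags) == ledger.clean_reads
    assert ledger_accounting(ledger)["verdict"] == "consistent"
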
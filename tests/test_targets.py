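"""Duplex penalty scoring, transcript scanning and concordance labels."""

import math

import numpy as np
import pytest

from srnapipe._seq import revcomp
from srnapipe.diffexpr import DifferentialCall
from srnapipe.targets import (
    _scan_scores_impl,
    _codes,
    concordance_report,
    scan_transcript,
    score_duplex,
)

from oracles import duplex_oracle

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def test_perfect_complement_scores_zero():
    score, (am, al, asite) = score_duplex(MIRNA, revcomp(MIRNA))
    assert score == 0.0
    assert set(al) == {"|"}
    assert am == MIRNA
    assert asite == revcomp(MIRNA)[::-1]


def test_single_wobble_costs_half():
    # miRNA G opposite target T is a G:U wobble
    i = MIRNA.index("G")
    site = list(revcomp(MIRNA))
    site[len(site) - 1 - i] = "T"
    score, (_, al, _) = score_duplex(MIRNA, "".join(site))
    assert score == 0.5
    assert al.count("o") == 1


def test_two_mismatches_plus_wobble():
    site = list(revcomp(MIRNA))
    n = len(site)
    iG = MIRNA.index("G")
    site[n - 1 - iG] = "T"                      # wobble
    # two real mismatches: bases that neither complement nor wobble
    for i in (2, 7):
        b = MIRNA[i]
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[b]
        site[n - 1 - i] = bad
    score, _ = score_duplex(MIRNA, "".join(site))
    assert score == 2.5


def test_scores_move_in_half_steps():
    rng = np.random.default_rng(3)
    for _ in range(30):
        m = "".join(rng.choice(list("ACGT"), size=12))
        s = "".join(rng.choice(list("ACGT"), size=12))
        score, _ = score_duplex(m, s)
        assert math.isclose(score * 2, round(score * 2))


def test_matches_brute_force_enumeration():
    """DP equals plain recursive enumeration of all gapped alignments."""
    rng = np.random.default_rng(29)
    for _ in range(80):
        lm = int(rng.integers(6, 13))
        ls = lm + int(rng.integers(-2, 3))
        m = "".join(rng.choice(list("ACGT"), size=lm))
        s = "".join(rng.choice(list("ACGT"), size=max(1, ls)))
        got, _ = score_duplex(m, s)
        assert got == pytest.approx(duplex_oracle(m, s))


def test_reversal_with_role_swap_preserves_score():
    """The physical duplex does not change when the two strands swap roles,
    so reversing both sequences and exchanging them preserves the score."""
    rng = np.random.default_rng(31)
    for _ in range(20):
        m = "".join(rng.choice(list("ACGT"), size=12))
        s = "".join(rng.choice(list("ACGT"), size=12))
        assert score_duplex(m, s)[0] == score_duplex(s[::-1], m[::-1])[0]


def test_adding_a_mismatch_never_lowers_the_score():
    rng = np.random.default_rng(37)
    site = revcomp(MIRNA)
    base_score, _ = score_duplex(MIRNA, site)
    for _ in range(15):
        i = int(rng.integers(0, len(site)))
        opposite = MIRNA[len(MIRNA) - 1 - i]
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[opposite]
        mutated = site[:i] + bad + site[i + 1 :]
        assert score_duplex(MIRNA, mutated)[0] >= base_score


def test_invalid_alphabet_rejected():
    with pytest.raises(ValueError):
        score_duplex("ACGTN" + MIRNA[5:], revcomp(MIRNA))


def test_vectorised_scan_agrees_with_scalar_scorer():
    rng = np.random.default_rng(41)
    m = "".join(rng.choice(list("ACGT"), size=19))
    t = "".join(rng.choice(list("ACGT"), size=120))
    a, tc = _codes(m, "m"), _codes(t, "t")
    for L in (17, 19, 21):
        scores = _scan_scores_impl(a, tc, L, 4, 2)
        for s in range(0, len(t) - L + 1, 7):
            assert scores[s] / 2.0 == score_duplex(m, t[s : s + L])[0]


class TestScan:
    def test_planted_perfect_site_found_once(self):
        rng = np.random.default_rng(43)
        t = "".join(rng.choice(list("ACGT"), size=400))
        site = revcomp(MIRNA)
        t = t[:150] + site + t[150:]
        hits = scan_transcript("m", MIRNA, "tx", t)
        assert len(hits) >= 1
        best = hits[0]
        assert best.score == 0.0
        assert (best.start, best.end) == (150, 150 + len(site))

    def test_random_sequences_rarely_hit_at_default_cutoff(self):
        rng = np.random.default_rng(47)
        total = 0
        for _ in range(10):
            m = "".join(rng.choice(list("ACGT"), size=21))
            t = "".join(rng.choice(list("ACGT"), size=1000))
            total += len(scan_transcript("m", m, "tx", t))
        assert total == 0

    def test_cutoff_zero_keeps_only_perfect_complements(self):
        rng = np.random.default_rng(53)
        t = "".join(rng.choice(list("ACGT"), size=300))
        t = t[:100] + revcomp(MIRNA) + t[100:]
        hits = scan_transcript("m", MIRNA, "tx", t, cutoff=0.0)
        assert [h.score for h in hits] == [0.0]

    def test_transcript_shorter_than_mirna_gives_empty(self):
        assert scan_transcript("m", MIRNA, "tx", "ACGT") == []


def _call(mid, lfc):
    return DifferentialCall(mid, 0, 0, 1e6, 1e6, 0, 0, lfc, 0.001, 0.01,
                            "up" if lfc > 0 else "down")


class TestConcordance:
    def _hits(self):
        from srnapipe.targets import TargetHit
        return [TargetHit("m1", "t1", 0, 21, 0.0, "", "", ""),
                TargetHit("m1", "t2", 0, 21, 0.0, "", "", ""),
                TargetHit("m1", "t3", 0, 21, 0.0, "", "", ""),
                TargetHit("m1", "t4", 0, 21, 0.0, "", "", "")]

    def test_sign_relations(self):
        rep = concordance_report(
            [_call("m1", 2.0)], self._hits(),
            {"t1": -2.0, "t2": 1.5, "t3": 0.0})
        rel = dict(zip(rep["transcript_id"], rep["relation"]))
        assert rel == {"t1": "opposite", "t2": "same", "t3": "flat", "t4": "missing"}
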
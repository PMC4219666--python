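"""Synthetic-study generator: determinism, invariants, planted truth."""

import numpy as np
import pytest

from srnapipe import preprocess, simdata
from srnapipe._seq import DNA, revcomp
from srnapipe.mirna_novel import evaluate_hairpin

from conftest import small_sim_config


def test_reference_counts_match_request():
    cfg = small_sim_config()
    cfg.n_known_mirnas = 5
    bundle = simdata.generate_reference(cfg)
    assert len(bundle.mature_mirnas) == 5
    assert len(bundle.ncrnas) == cfg.n_ncrnas
    assert len(bundle.transcripts) == cfg.n_transcripts
    assert len(bundle.novel) == cfg.n_novel_hairpins


def test_reference_determinism(small_config):
    b1 = simdata.generate_reference(small_config)
    b2 = simdata.generate_reference(small_config)
    assert b1.mature_mirnas == b2.mature_mirnas
    assert b1.transcripts == b2.transcripts
    assert b1.hairpins == b2.hairpins


def test_bundle_invariants(small_bundle):
    """Matures occur verbatim in their hairpins on the stated arm; ids are
    unique across the bundle; the alphabet is DNA."""
    ids = (list(small_bundle.mature_mirnas) + list(small_bundle.ncrnas)
           + list(small_bundle.transcripts))
    assert len(ids) == len(set(ids))
    for mid, seq in small_bundle.mature_mirnas.items():
        assert 18 <= len(seq) <= 26
        assert set(seq) <= set(DNA)
        pre, s, e, arm = small_bundle.hairpins[mid]
        assert pre[s:e] == seq
        assert 60 <= len(pre) <= 200
        mid_point = len(pre) / 2
        assert (e <= mid_point) if arm == "5p" else (s >= mid_point)
    for seq, cat in small_bundle.ncrnas.values():
        assert cat in ("rRNA", "tRNA", "snRNA", "snoRNA")
        assert set(seq) <= set(DNA)


def test_planted_hairpins_pass_their_own_screen(small_bundle):
    """Generator positive controls: every planted precursor is accepted,
    and it sits in its transcript in the recorded orientation."""
    for tr in small_bundle.novel.values():
        cand = evaluate_hairpin(tr.precursor, (tr.mature_start, tr.mature_end))
        assert cand.verdict == "accept"
        assert cand.arm == tr.arm
        embedded = small_bundle.transcripts[tr.transcript_id][tr.start:tr.end]
        expected = tr.precursor if tr.strand == "+" else revcomp(tr.precursor)
        assert embedded == expected


def test_planted_target_sites_are_perfect_complements(small_bundle):
    for mid, tid, pos in small_bundle.target_sites:
        m = small_bundle.mature_mirnas[mid]
        assert small_bundle.transcripts[tid][pos : pos + len(m)] == revcomp(m)


def test_invalid_config_errors_name_the_field():
    cfg = small_sim_config()
    cfg.abundance_dispersion = 0.0
    with pytest.raises(ValueError, match="abundance_dispersion"):
        cfg.validate()
    cfg = small_sim_config()
    cfg.length_mode_weights = {24: 0.5}
    with pytest.raises(ValueError, match="length_mode_weights"):
        cfg.validate()
    cfg = small_sim_config()
    cfg.contamination_rates = {"polyA": 1.5}
    with pytest.raises(ValueError, match="contamination_rates"):
        cfg.validate()
    cfg = small_sim_config()
    cfg.de_subset = [("x", "frost", 2.0)]
    with pytest.raises(ValueError, match="de_subset"):
        cfg.validate()


def test_unknown_condition_label_rejected(small_config, small_bundle):
    with pytest.raises(ValueError, match="unknown condition"):
        simdata.generate_library(small_bundle, small_config, "frost")


def test_library_count_and_determinism(small_config, small_bundle, tmp_path):
    rec1, truth1 = simdata.generate_library(
        small_bundle, small_config, "control", tmp_path / "a.fastq")
    rec2, _ = simdata.generate_library(
        small_bundle, small_config, "control", tmp_path / "b.fastq")
    assert len(rec1) == small_config.n_reads_per_library
    assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
    assert len(truth1) == len(rec1)


def test_zero_contamination_gives_empty_removal_categories(small_bundle):
    cfg = small_sim_config(seed=5, n_reads=1500)
    cfg.contamination_rates = {c: 0.0 for c in simdata.CONTAMINATION_CATEGORIES}
    cfg.low_quality_rate = 0.0
    records, _ = simdata.generate_library(small_bundle, cfg, "control")
    _, ledger = preprocess.clean_reads(records, cfg.adapter_5p, cfg.adapter_3p)
    assert ledger.removals() == 0
    assert ledger.clean_reads == ledger.high_quality == ledger.raw_reads


def test_truth_category_frequencies_match_rates(small_config, small_bundle):
    """Observed contamination frequencies converge on the configured rates
    (within 3 binomial standard errors)."""
    cfg = small_sim_config(seed=9, n_reads=20_000)
    _, truth = simdata.generate_library(small_bundle, cfg, "control")
    n = len(truth)
    freq = truth["category"].value_counts() / n
    for cat, p in cfg.contamination_rates.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq.get(cat, 0.0) - p) <= 3 * se + 1e-12


def test_clean_inserts_trace_to_their_source(small_config, small_bundle):
    """Every miRNA-category read's insert is exactly its source's mature."""
    records, truth = simdata.generate_library(small_bundle, small_config, "control")
    reads = {rid: seq for rid, seq, _ in records}
    mir = truth[truth["category"] == "miRNA"]
    assert len(mir) > 0
    a5 = small_config.adapter_5p
    for rid, src in zip(mir["read_id"], mir["source_id"]):
        mature = small_bundle.mature_mirnas[src]
        assert reads[rid][len(a5) : len(a5) + len(mature)] == mature


def test_modal_insert_length_is_24(small_library):
    tags, _, _ = small_library
    df = preprocess.length_distribution(tags)
    top = df.sort_values("proportion", ascending=False).iloc[0]
    assert top["length"] == 24


def test_de_subset_shifts_expected_counts():
    """A planted 4-fold effect is recovered within 25% at adequate depth."""
    cfg = small_sim_config(seed=11, n_reads=30_000)
    bundle = simdata.generate_reference(cfg)
    ranked = sorted(bundle.mirna_abundance, key=bundle.mirna_abundance.get)
    mid = ranked[-1]  # most abundant, so sampling error is small
    cfg.de_subset = [(mid, "drought", 4.0)]
    _, t_ctrl = simdata.generate_library(bundle, cfg, "control")
    _, t_drt = simdata.generate_library(bundle, cfg, "drought")
    x = (t_ctrl["source_id"] == mid).sum()
    y = (t_drt["source_id"] == mid).sum()
    assert x > 100
    assert abs(y / x - 4.0) <= 1.0
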
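"""Seeded synthetic references and three-condition raw sRNA libraries.

The generator emulates the statistical structure of an unreplicated plant
stress small-RNA experiment: one library per condition (control,
saline-alkali, drought), a read-length distribution with a major mode at
24 nt and a minor mode at 20/21 nt, adapter-ligated reads carrying five
classes of removable contamination, known-miRNA tags with log-normally
dispersed abundances, novel-miRNA hairpins planted inside transcript
contigs, perfect-complement target sites planted for designated miRNAs, and
condition-dependent fold-changes for a configurable DE subset.

Everything is deterministic under a fixed seed: the same config yields
byte-identical FASTA/FASTQ output.  A sidecar truth table records, per read,
the source record and category so downstream recovery can be measured.

Sequences are held in the DNA alphabet throughout (T, not U); see _seq.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from srnapipe._seq import DNA, revcomp

CONDITIONS = ("control", "saline_alkali", "drought")

CONTAMINATION_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminant",
    "shorter_than_18nt",
    "polyA",
)

# Default insert-length weights (18-30 nt): major mode at 24, minor at 20/21.
DEFAULT_LENGTH_WEIGHTS = {
    18: 0.02, 19: 0.03, 20: 0.14, 21: 0.13, 22: 0.08, 23: 0.07,
    24: 0.30, 25: 0.06, 26: 0.05, 27: 0.04, 28: 0.03, 29: 0.03, 30: 0.02,
}

# Adapters as ligated in the emulated protocol, DNA form.
DEFAULT_ADAPTER_5P = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER_3P = "GTTCAGAGTTCTACAGTCCGACGATC"

# Contamination rates roughly proportional to the category shares observed
# in deep plant sRNA libraries (a few percent removed overall).
DEFAULT_CONTAMINATION = {
    "adapter3_null": 0.015,
    "insert_null": 0.0005,
    "adapter5_contaminant": 0.008,
    "shorter_than_18nt": 0.009,
    "polyA": 0.0005,
}

# Share of clean reads per source class: ~32% ncRNA, ~10% known miRNA, a few
# percent novel-miRNA matures, the rest mRNA-degradation fragments and
# unclassifiable sequence.
DEFAULT_CLASS_SHARES = {
    "miRNA": 0.10,
    "novel": 0.03,
    "rRNA": 0.14,
    "tRNA": 0.10,
    "snRNA": 0.04,
    "snoRNA": 0.04,
    "mrna_fragment": 0.10,
    "random": 0.45,
}

_PLANT_FAMILIES = (156, 159, 160, 164, 166, 167, 168, 169, 171, 172,
                   319, 390, 393, 394, 396, 397, 399, 408, 444, 827)


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults describe the emulated study conditions; the per-library depth is
    a free parameter (the emulated protocol reports depth only per run).
    """

    seed: int = 0
    n_reads_per_library: int = 50_000
    length_mode_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    adapter_5p: str = DEFAULT_ADAPTER_5P
    adapter_3p: str = DEFAULT_ADAPTER_3P
    contamination_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINATION))
    low_quality_rate: float = 0.026
    n_known_mirnas: int = 30
    n_novel_hairpins: int = 8
    n_ncrnas: int = 40
    n_transcripts: int = 30
    n_target_sites: int = 10
    de_subset: list[tuple[str, str, float]] = field(default_factory=list)
    abundance_dispersion: float = 2.0
    class_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SHARES))
    read_length: int = 60

    def validate(self) -> None:
        if self.n_reads_per_library <= 0:
            raise ValueError("invalid config field n_reads_per_library: must be positive")
        for name in ("n_known_mirnas", "n_novel_hairpins", "n_ncrnas",
                     "n_transcripts", "n_target_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config field {name}: must be >= 0")
        if self.abundance_dispersion <= 0:
            raise ValueError("invalid config field abundance_dispersion: must be > 0")
        if not self.adapter_5p or not self.adapter_3p:
            raise ValueError("invalid config field adapter_5p/adapter_3p: must be non-empty")
        w = self.length_mode_weights
        if not w or any(not (18 <= k <= 30) for k in w):
            raise ValueError("invalid config field length_mode_weights: lengths must be 18-30")
        if any(p < 0 for p in w.values()) or abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("invalid config field length_mode_weights: must sum to 1")
        for cat, p in self.contamination_rates.items():
            if cat not in CONTAMINATION_CATEGORIES:
                raise ValueError(f"invalid config field contamination_rates: unknown category {cat}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"invalid config field contamination_rates[{cat}]: not in [0,1]")
        if not 0.0 <= self.low_quality_rate <= 1.0:
            raise ValueError("invalid config field low_quality_rate: not in [0,1]")
        if sum(self.contamination_rates.values()) + self.low_quality_rate >= 1.0:
            raise ValueError("invalid config field contamination_rates: total rate >= 1")
        for mid, cond, fc in self.de_subset:
            if cond not in CONDITIONS:
                raise ValueError(f"invalid config field de_subset: unknown condition {cond}")
            if fc <= 0:
                raise ValueError(f"invalid config field de_subset: fold-change for {mid} must be > 0")
        shares = self.class_shares
        if any(p < 0 for p in shares.values()) or abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ValueError("invalid config field class_shares: must sum to 1")
        if self.read_length < len(self.adapter_5p) + 30 + 9:
            raise ValueError("invalid config field read_length: too short for adapters + insert")


@dataclass
class HairpinTruth:
    """Where a planted hairpin lives and what its mature product is."""

    mature: str
    arm: str                 # "5p" or "3p"
    strand: str              # orientation of the hairpin on its contig
    transcript_id: str
    start: int               # precursor span on the contig, 0-based half-open
    end: int
    precursor: str
    mature_start: int        # mature span within the precursor
    mature_end: int


@dataclass
class ReferenceBundle:
    """Synthetic reference sets standing in for the miRNA/ncRNA databases
    and the transcript (unigene) assembly."""

    mature_mirnas: dict[str, str]
    hairpins: dict[str, tuple[str, int, int, str]]  # id -> (precursor, start, end, arm)
    ncrnas: dict[str, tuple[str, str]]              # id -> (sequence, category)
    transcripts: dict[str, str]
    mirna_abundance: dict[str, float]               # baseline relative weights
    novel: dict[str, HairpinTruth] = field(default_factory=dict)
    target_sites: list[tuple[str, str, int]] = field(default_factory=list)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def _clean_tag_ok(seq: str, cfg: SimConfig) -> bool:
    """A planted clean tag must survive the cleaning filters untouched."""
    if cfg.adapter_5p[:8] in seq or cfg.adapter_3p[:8] in seq:
        return False
    return seq.count("A") / len(seq) < 0.8


def _draw_clean_tag(rng: np.random.Generator, n: int, cfg: SimConfig) -> str:
    while True:
        s = _rand_seq(rng, n)
        if _clean_tag_ok(s, cfg):
            return s


_WEAK = "CT"  # loop/flank alphabet that cannot pair with itself


def _build_hairpin(rng: np.random.Generator, mature: str, arm: str,
                   cfg: SimConfig) -> tuple[str, int, int]:
    """A perfect-stem precursor carrying ``mature`` entirely on one arm.

    Layout: flank5 + stemL + loop + revcomp(stemL) + flank3.  The loop and
    flanks use a {C,T} alphabet so they cannot pair among themselves, making
    the full stem the unique optimal fold.
    """
    ext = _draw_clean_tag(rng, int(rng.integers(12, 19)), cfg)
    loop = "".join(_WEAK[i] for i in rng.integers(0, 2, size=8))
    f5 = "".join(_WEAK[i] for i in rng.integers(0, 2, size=int(rng.integers(3, 7))))
    f3 = "".join(_WEAK[i] for i in rng.integers(0, 2, size=int(rng.integers(3, 7))))
    if arm == "5p":
        stem_l = mature + ext
        m_start = len(f5)
    else:
        right_arm = ext + mature           # mature sits on the 3p arm
        stem_l = revcomp(right_arm)
        m_start = len(f5) + len(stem_l) + len(loop) + len(ext)
    precursor = f5 + stem_l + loop + revcomp(stem_l) + f3
    return precursor, m_start, m_start + len(mature)


def generate_reference(config: SimConfig) -> ReferenceBundle:
    """Build the full synthetic reference bundle for ``config``.

    Known matures get perfect-stem hairpins; novel hairpins are spliced into
    transcript contigs (reverse-complemented for minus-strand plantings);
    designated target transcripts carry a perfect-complement site for their
    miRNA, so the duplex score at the planted site is 0.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    # --- known mature miRNAs grouped into plant-style families ------------
    mature: dict[str, str] = {}
    fam_idx, letter = 0, 0
    lengths = np.array([20, 21, 22, 24])
    lprobs = np.array([0.3, 0.3, 0.1, 0.3])
    seen: set[str] = set()
    while len(mature) < config.n_known_mirnas:
        fam = _PLANT_FAMILIES[fam_idx % len(_PLANT_FAMILIES)]
        mid = f"lch-miR{fam}{chr(ord('a') + letter)}"
        n = int(rng.choice(lengths, p=lprobs))
        s = _draw_clean_tag(rng, n, config)
        if s in seen:
            continue
        seen.add(s)
        mature[mid] = s
        fam_idx += 1
        if fam_idx % len(_PLANT_FAMILIES) == 0:
            letter += 1

    # baseline abundances: log-normal spread (some tags orders of magnitude
    # more abundant than others, as real libraries show)
    z = rng.normal(0.0, config.abundance_dispersion, size=len(mature))
    abundance = {mid: float(np.exp(v)) for mid, v in zip(sorted(mature), z)}

    hairpins = {}
    for mid, seq in mature.items():
        arm = "5p" if rng.random() < 0.5 else "3p"
        pre, s, e = _build_hairpin(rng, seq, arm, config)
        hairpins[mid] = (pre, s, e, arm)

    # --- ncRNA references -------------------------------------------------
    ncrnas: dict[str, tuple[str, str]] = {}
    cats = ("rRNA", "tRNA", "snRNA", "snoRNA")
    for i in range(config.n_ncrnas):
        cat = cats[i % len(cats)]
        n = int(rng.integers(80, 501))
        ncrnas[f"{cat}-{i + 1:03d}"] = (_rand_seq(rng, n), cat)

    # --- transcript contigs ----------------------------------------------
    transcripts = {
        f"GW_c{10000 + i:05d}": _rand_seq(rng, int(rng.integers(200, 2001)))
        for i in range(config.n_transcripts)
    }
    tids = sorted(transcripts)

    # --- novel hairpins planted inside transcripts ------------------------
    # rejection-sample each planting until its own precursor passes the
    # screening criteria: the optimal fold can otherwise tie the intended
    # perfect stem with alternatives that bulge the mature duplex
    from srnapipe.mirna_novel import evaluate_hairpin

    novel: dict[str, HairpinTruth] = {}
    for i in range(config.n_novel_hairpins):
        arm = "5p" if rng.random() < 0.5 else "3p"
        strand = "+" if rng.random() < 0.5 else "-"
        for _attempt in range(100):
            m = _draw_clean_tag(rng, int(rng.integers(20, 24)), config)
            pre, ms, me = _build_hairpin(rng, m, arm, config)
            if evaluate_hairpin(pre, (ms, me)).verdict == "accept":
                break
        else:
            raise RuntimeError("could not plant an acceptable hairpin in 100 attempts")
        tid = tids[int(rng.integers(0, len(tids)))]
        t = transcripts[tid]
        pos = int(rng.integers(0, len(t) + 1))
        embed = pre if strand == "+" else revcomp(pre)
        transcripts[tid] = t[:pos] + embed + t[pos:]
        novel[f"novel-{i + 1:02d}"] = HairpinTruth(
            mature=m, arm=arm, strand=strand, transcript_id=tid,
            start=pos, end=pos + len(pre), precursor=pre,
            mature_start=ms, mature_end=me,
        )

    # --- perfect-complement target sites ----------------------------------
    target_sites: list[tuple[str, str, int]] = []
    mids = sorted(mature)
    if config.n_target_sites and mids:
        for i in range(config.n_target_sites):
            mid = mids[int(rng.integers(0, len(mids)))]
            tid = tids[int(rng.integers(0, len(tids)))]
            site = revcomp(mature[mid])
            t = transcripts[tid]
            pos = int(rng.integers(0, len(t) + 1))
            transcripts[tid] = t[:pos] + site + t[pos:]
            # earlier plantings on the same contig keep their coordinates
            # only if they precede this insertion point; re-derive spans
            for tr in novel.values():
                if tr.transcript_id == tid and tr.start >= pos:
                    tr.start += len(site)
                    tr.end += len(site)
            target_sites = [
                (m0, t0, p0 + len(site)) if t0 == tid and p0 >= pos else (m0, t0, p0)
                for m0, t0, p0 in target_sites
            ]
            target_sites.append((mid, tid, pos))

    return ReferenceBundle(
        mature_mirnas=mature,
        hairpins=hairpins,
        ncrnas=ncrnas,
        transcripts=transcripts,
        mirna_abundance=abundance,
        novel=novel,
        target_sites=target_sites,
    )


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def _fragment_pool(rng: np.random.Generator, sources: list[tuple[str, str]],
                   n_frags: int, cfg: SimConfig) -> list[tuple[str, str]]:
    """Distinct substrings of reference sequences, usable as clean tags."""
    lengths = sorted(cfg.length_mode_weights)
    probs = np.array([cfg.length_mode_weights[k] for k in lengths])
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n_frags and attempts < 50 * n_frags:
        attempts += 1
        sid, seq = sources[int(rng.integers(0, len(sources)))]
        n = int(rng.choice(lengths, p=probs))
        if len(seq) <= n:
            continue
        start = int(rng.integers(0, len(seq) - n + 1))
        frag = seq[start : start + n]
        if frag in seen or not _clean_tag_ok(frag, cfg):
            continue
        seen.add(frag)
        out.append((sid, frag))
    return out


def _build_tag_pool(bundle: ReferenceBundle, cfg: SimConfig):
    """Deterministic pool of clean tags with baseline weights.

    Returns (sequences, source_ids, categories, weights); weights embed the
    class shares, so sampling the pool directly reproduces the configured
    composition in expectation.
    """
    rng = np.random.default_rng([cfg.seed, 202])
    seqs: list[str] = []
    srcs: list[str] = []
    cats: list[str] = []
    wts: list[float] = []

    def add_class(entries: list[tuple[str, str]], cat: str, share: float,
                  sigma: float) -> None:
        if not entries or share <= 0:
            return
        w = np.exp(rng.normal(0.0, sigma, size=len(entries)))
        w = w / w.sum() * share
        for (sid, s), wi in zip(entries, w):
            seqs.append(s)
            srcs.append(sid)
            cats.append(cat)
            wts.append(float(wi))

    shares = cfg.class_shares
    mir_entries = [(mid, s) for mid, s in sorted(bundle.mature_mirnas.items())]
    # use the bundle's baseline abundances for known miRNAs
    if mir_entries and shares.get("miRNA", 0) > 0:
        w = np.array([bundle.mirna_abundance[mid] for mid, _ in mir_entries])
        w = w / w.sum() * shares["miRNA"]
        for (mid, s), wi in zip(mir_entries, w):
            seqs.append(s)
            srcs.append(mid)
            cats.append("miRNA")
            wts.append(float(wi))

    add_class([(nid, tr.mature) for nid, tr in sorted(bundle.novel.items())],
              "novel", shares.get("novel", 0), 0.8)

    by_cat: dict[str, list[tuple[str, str]]] = {c: [] for c in ("rRNA", "tRNA", "snRNA", "snoRNA")}
    for nid, (seq, cat) in bundle.ncrnas.items():
        by_cat[cat].append((nid, seq))
    for cat in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        frags = _fragment_pool(rng, sorted(by_cat[cat]), 80, cfg)
        add_class(frags, cat, shares.get(cat, 0), 1.0)

    tx = sorted(bundle.transcripts.items())
    add_class(_fragment_pool(rng, tx, 400, cfg), "mrna_fragment",
              shares.get("mrna_fragment", 0), 1.0)

    lengths = sorted(cfg.length_mode_weights)
    probs = np.array([cfg.length_mode_weights[k] for k in lengths])
    n_random = 4000
    rand_entries = []
    seen = set(seqs)
    while len(rand_entries) < n_random:
        n = int(rng.choice(lengths, p=probs))
        s = _draw_clean_tag(rng, n, cfg)
        if s in seen:
            continue
        seen.add(s)
        rand_entries.append((f"unassigned-{len(rand_entries) + 1:05d}", s))
    add_class(rand_entries, "random", shares.get("random", 0), 0.5)

    return seqs, srcs, cats, np.array(wts)


def _quality_string(rng: np.random.Generator, n: int, low: bool) -> str:
    if not low:
        return "I" * n                      # Phred 40
    ph = rng.integers(2, 15, size=n)        # well below the Q20 mean gate
    return "".join(chr(33 + int(p)) for p in ph)


def generate_library(
    bundle: ReferenceBundle,
    config: SimConfig,
    condition: str,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emit one condition's raw FASTQ library plus its per-read truth table.

    Reads are ``adapter_5p + insert + adapter_3p`` truncated to the read
    length, with contamination classes injected at the configured rates and
    the DE subset's fold-changes applied to that condition's expected tag
    counts.  Returns (records, truth); records are (id, sequence, quality).
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition label: {condition!r}")
    cond_idx = CONDITIONS.index(condition)
    rng = np.random.default_rng([config.seed, 303, cond_idx])

    seqs, srcs, cats, weights = _build_tag_pool(bundle, config)
    weights = weights.copy()
    for mid, cond, fc in config.de_subset:
        if cond != condition:
            continue
        hit = [i for i, s in enumerate(srcs) if s == mid]
        if not hit:
            raise ValueError(f"de_subset miRNA {mid!r} not in reference bundle")
        for i in hit:
            weights[i] *= fc
    probs = weights / weights.sum()

    a5, a3 = config.adapter_5p, config.adapter_3p
    rlen = config.read_length
    fate_labels = ["clean", "low_quality", *CONTAMINATION_CATEGORIES]
    fate_p = np.array(
        [1.0 - config.low_quality_rate - sum(config.contamination_rates.values()),
         config.low_quality_rate]
        + [config.contamination_rates.get(c, 0.0) for c in CONTAMINATION_CATEGORIES]
    )
    n = config.n_reads_per_library
    fates = rng.choice(len(fate_labels), size=n, p=fate_p)
    # draw pool indices for every read up front; contaminant reads ignore them
    pool_idx = rng.choice(len(seqs), size=n, p=probs)

    lengths = sorted(config.length_mode_weights)
    lp = np.array([config.length_mode_weights[k] for k in lengths])

    records: list[tuple[str, str, str]] = []
    truth_rows: list[tuple[str, str, str]] = []
    a3_seed = a3[:8]
    for i in range(n):
        rid = f"{condition}_{i + 1:07d}"
        fate = fate_labels[fates[i]]
        if fate in ("clean", "low_quality"):
            j = int(pool_idx[i])
            insert = seqs[j]
            src, cat = (srcs[j], cats[j]) if fate == "clean" else (srcs[j], "low_quality")
            read = (a5 + insert + a3)[:rlen]
            qual = _quality_string(rng, len(read), fate == "low_quality")
        elif fate == "adapter3_null":
            insert = _draw_clean_tag(rng, int(rng.choice(lengths, p=lp)), config)
            while True:
                junk = _rand_seq(rng, rlen)
                body = insert + junk
                if a3_seed not in body:
                    break
            read = (a5 + body)[:rlen]
            qual = _quality_string(rng, len(read), False)
            src, cat = fate, fate
        elif fate == "insert_null":
            read = (a5 + a3)[:rlen]
            qual = _quality_string(rng, len(read), False)
            src, cat = fate, fate
        elif fate == "adapter5_contaminant":
            core = a5[:8]
            pre = _rand_seq(rng, 5)
            post = _rand_seq(rng, 8)
            insert = pre + core + post
            read = (a5 + insert + a3)[:rlen]
            qual = _quality_string(rng, len(read), False)
            src, cat = fate, fate
        elif fate == "shorter_than_18nt":
            insert = _rand_seq(rng, int(rng.integers(1, 18)))
            while a3_seed in insert or a5[:8] in insert:
                insert = _rand_seq(rng, len(insert))
            read = (a5 + insert + a3)[:rlen]
            qual = _quality_string(rng, len(read), False)
            src, cat = fate, fate
        else:  # polyA
            insert = "A" * int(rng.choice(lengths, p=lp))
            read = (a5 + insert + a3)[:rlen]
            qual = _quality_string(rng, len(read), False)
            src, cat = fate, fate
        records.append((rid, read, qual))
        truth_rows.append((rid, src, cat))

    truth = pd.DataFrame(truth_rows, columns=["read_id", "source_id", "category"])
    if fastq_path is not None:
        write_fastq(records, fastq_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return records, truth


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_reference_fastas(bundle: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as FASTA files (matures, hairpins, ncRNAs, transcripts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def dump(name: str, entries: list[tuple[str, str]]) -> None:
        p = outdir / f"{name}.fasta"
        with open(p, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        paths[name] = p

    dump("mature", sorted(bundle.mature_mirnas.items()))
    dump("hairpin", [(mid, h[0]) for mid, h in sorted(bundle.hairpins.items())])
    dump("ncrna", [(f"{nid} {cat}", seq) for nid, (seq, cat) in sorted(bundle.ncrnas.items())])
    dump("transcripts", sorted(bundle.transcripts.items()))
    return paths


def make_demo_config(seed: int = 0, n_reads: int = 50_000,
                     n_de: int = 6, fold_change: float = 4.0) -> tuple[SimConfig, ReferenceBundle]:
    """Default demo study: three libraries with a planted DE subset.

    The DE subset is drawn from the upper half of the baseline abundance
    distribution (differential calls are only meaningful for expressed
    miRNAs); half the effects are up, half down, split between the two
    stress conditions.
    """
    cfg = SimConfig(seed=seed, n_reads_per_library=n_reads)
    bundle = generate_reference(cfg)
    ranked = sorted(bundle.mirna_abundance, key=bundle.mirna_abundance.get, reverse=True)
    top = ranked[: max(n_de, len(ranked) // 2)]
    rng = np.random.default_rng([seed, 404])
    chosen = list(rng.choice(top, size=min(n_de, len(top)), replace=False))
    de = []
    for i, mid in enumerate(chosen):
        cond = CONDITIONS[1 + i % 2]
        fc = fold_change if i % 2 == 0 else 1.0 / fold_change
        de.append((str(mid), cond, fc))
    cfg.de_subset = de
    return cfg, bundle
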
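"""End-to-end orchestration: simulate -> clean -> annotate -> known ->
novel -> differential expression -> targets -> concordance -> recovery.

A single YAML-able config drives every stage; all thresholds the analysis
depends on (identity 0.95, coverage 0.90, p 0.01, fold-change 2, MFE -18,
target cutoff 3.5) are surfaced in the config with those values as
defaults.  Reports are plain TSV/JSON; reruns under the same config and
seed produce byte-identical reports (the run manifest additionally records
wall-clock timestamps and is excluded from that guarantee).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import srnapipe
from srnapipe import annotate as annotate_mod
from srnapipe import diffexpr as diffexpr_mod
from srnapipe import mirna_known, mirna_novel, preprocess, simdata, targets as targets_mod
from srnapipe.preprocess import LEDGER_ROW_NAMES

log = logging.getLogger("srnapipe")

DEFAULT_THRESHOLDS = {
    "identity": 0.95,
    "coverage": 0.90,
    "p_value": 0.01,
    "fold_change": 2.0,
    "mfe": -18.0,
    "target_cutoff": 3.5,
}


def default_config(seed: int = 0, n_reads: int = 50_000) -> dict:
    """The synthetic demo configuration: three libraries, planted DE subset."""
    return {
        "seed": seed,
        "simulate": {"n_reads_per_library": n_reads, "demo_de": {"n_de": 6, "fold_change": 4.0}},
        "thresholds": dict(DEFAULT_THRESHOLDS),
    }


def validate_config(config: dict) -> list[str]:
    """Return the list of violations (empty means ok)."""
    v: list[str] = []
    th = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    if not 0 < th["identity"] <= 1:
        v.append("thresholds.identity must be in (0, 1]")
    if not 0 < th["coverage"] <= 1:
        v.append("thresholds.coverage must be in (0, 1]")
    if not 0 < th["p_value"] <= 1:
        v.append("thresholds.p_value must be in (0, 1]")
    if th["fold_change"] <= 1:
        v.append("thresholds.fold_change must be > 1")
    if th["mfe"] >= 0:
        v.append("thresholds.mfe must be negative")
    if th["target_cutoff"] < 0:
        v.append("thresholds.target_cutoff must be >= 0")
    if "simulate" not in config and "inputs" not in config:
        v.append("config needs a 'simulate' section or an 'inputs' section")
    for key, path in config.get("inputs", {}).items():
        if isinstance(path, dict):
            for lib, p in path.items():
                if not Path(p).exists():
                    v.append(f"inputs.{key}.{lib}: file not found: {p}")
        elif not Path(path).exists():
            v.append(f"inputs.{key}: file not found: {path}")
    sim = config.get("simulate", {})
    if sim:
        cfg = _sim_config(config)
        try:
            cfg.validate()
        except ValueError as exc:
            v.append(str(exc))
    return v


def _sim_config(config: dict) -> simdata.SimConfig:
    sim = dict(config.get("simulate", {}))
    sim.pop("demo_de", None)
    allowed = {f for f in simdata.SimConfig.__dataclass_fields__}
    unknown = set(sim) - allowed
    if unknown:
        raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
    return simdata.SimConfig(seed=config.get("seed", 0), **sim)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _simulate_target_expression(
    bundle: simdata.ReferenceBundle, cfg: simdata.SimConfig, condition: str
) -> dict[str, float]:
    """Synthetic transcript log2FC table for the concordance report.

    Transcripts carrying a planted site of a DE miRNA respond with the same
    sign as the miRNA in ~60% of cases, the opposite sign in ~25% and stay
    flat otherwise; all other transcripts get small noise around zero.
    """
    rng = np.random.default_rng([cfg.seed, 505, simdata.CONDITIONS.index(condition)])
    lfc = {tid: float(rng.normal(0.0, 0.3)) for tid in sorted(bundle.transcripts)}
    de = {mid: fc for mid, cond, fc in cfg.de_subset if cond == condition}
    for mid, tid, _pos in bundle.target_sites:
        if mid not in de:
            continue
        sign = 1.0 if de[mid] > 1 else -1.0
        u = rng.random()
        if u < 0.6:
            lfc[tid] = sign * float(rng.uniform(1.2, 3.0))
        elif u < 0.85:
            lfc[tid] = -sign * float(rng.uniform(1.2, 3.0))
        else:
            lfc[tid] = float(rng.uniform(-0.3, 0.3))
    return lfc


def load_reference_bundle(
    mature: str | Path,
    ncrna: str | Path,
    transcripts: str | Path,
) -> simdata.ReferenceBundle:
    """Build a ReferenceBundle from user FASTA files.

    ncRNA records carry their category (rRNA/tRNA/snRNA/snoRNA) as the
    first word of the description, miRBase-style headers are accepted for
    matures.  Hairpins and truth fields stay empty.
    """
    from Bio import SeqIO

    def _read(path):
        return [(r.id, str(r.seq).upper().replace("U", "T"), r.description)
                for r in SeqIO.parse(str(path), "fasta")]

    mat = {rid: seq for rid, seq, _ in _read(mature)}
    ncr = {}
    for rid, seq, desc in _read(ncrna):
        words = desc.split()
        cat = words[1] if len(words) > 1 else "rRNA"
        if cat not in ("rRNA", "tRNA", "snRNA", "snoRNA"):
            raise ValueError(f"ncRNA record {rid}: unknown category {cat!r}")
        ncr[rid] = (seq, cat)
    tx = {rid: seq for rid, seq, _ in _read(transcripts)}
    return simdata.ReferenceBundle(
        mature_mirnas=mat, hairpins={}, ncrnas=ncr, transcripts=tx,
        mirna_abundance={mid: 1.0 for mid in mat})


def run_all(config: dict, outdir: str | Path) -> dict:
    """Run every stage and write all report tables plus a run manifest.

    Raises RuntimeError naming the failing stage; on success returns the
    manifest dict (also written to manifest.json).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    seed = config.get("seed", 0)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": srnapipe.__version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------ simulate / load
        simulated = "inputs" not in config
        cfg = _sim_config(config)
        if simulated:
            stage = "simulate"
            demo = config.get("simulate", {}).get("demo_de")
            if demo and not cfg.de_subset:
                cfg, bundle = simdata.make_demo_config(
                    seed=seed, n_reads=cfg.n_reads_per_library,
                    n_de=demo.get("n_de", 6), fold_change=demo.get("fold_change", 4.0),
                )
            else:
                bundle = simdata.generate_reference(cfg)
            ref_paths = simdata.write_reference_fastas(bundle, outdir / "reference")
            libs = list(simdata.CONDITIONS)
            fastqs: dict[str, Path] = {}
            truths: dict[str, pd.DataFrame] = {}
            for cond in libs:
                fq = outdir / f"{cond}.fastq"
                tt = outdir / f"{cond}.truth.tsv"
                _, truth = simdata.generate_library(bundle, cfg, cond, fq, tt)
                fastqs[cond] = fq
                truths[cond] = truth
                log.info("simulate: %s -> %d reads", cond, len(truth))
            manifest["stages"]["simulate"] = {
                "outputs": {**{k: str(p) for k, p in ref_paths.items()},
                            **{c: str(p) for c, p in fastqs.items()}},
                "records": {c: int(len(truths[c])) for c in libs},
            }
        else:
            stage = "load"
            inputs = config["inputs"]
            bundle = load_reference_bundle(
                inputs["mature"], inputs["ncrna"], inputs["transcripts"])
            fastqs = {lib: Path(p) for lib, p in inputs["fastq"].items()}
            libs = list(fastqs)
            if "control" in libs:  # control first so DE contrasts are defined
                libs = ["control"] + [l for l in libs if l != "control"]
            manifest["stages"]["load"] = {"records": {
                "mature": len(bundle.mature_mirnas), "ncrna": len(bundle.ncrnas),
                "transcripts": len(bundle.transcripts)}}

        # ------------------------------------------------ clean
        stage = "clean"
        params = preprocess.CleanParams(**config.get("clean", {}))
        ledgers: dict[str, preprocess.FilterLedger] = {}
        per_lib_tags: dict[str, list[preprocess.SmallRNATag]] = {}
        for cond in libs:
            tags, ledger = preprocess.clean_reads(
                fastqs[cond], cfg.adapter_5p, cfg.adapter_3p, params, library=cond)
            ledgers[cond] = ledger
            per_lib_tags[cond] = tags
            acct = preprocess.ledger_accounting(ledger)
            log.info("clean: %s raw=%d clean=%d (%.2f%%) verdict=%s", cond,
                     ledger.raw_reads, ledger.clean_reads, acct["clean_pct"], acct["verdict"])
        tags = preprocess.merge_tag_tables(per_lib_tags)
        ledger_df = pd.DataFrame({c: ledgers[c].to_series() for c in libs})
        ledger_df.index.name = "category"
        ledger_df.to_csv(outdir / "ledger.tsv", sep="\t")
        tag_df = pd.DataFrame(
            [[t.sequence] + [t.counts.get(c, 0) for c in libs] for t in tags],
            columns=["sequence"] + libs)
        tag_df.to_csv(outdir / "tags.tsv", sep="\t", index=False)
        preprocess.length_distribution(tags).to_csv(
            outdir / "length_histogram.tsv", sep="\t", index=False)
        manifest["stages"]["clean"] = {
            "records": {c: ledgers[c].clean_reads for c in libs},
            "unique_tags": len(tags),
        }

        # ------------------------------------------------ annotate
        stage = "annotate"
        ann_th = annotate_mod.AnnotationThresholds(th["identity"], th["coverage"])
        annotation = annotate_mod.classify_tags(tags, bundle, ann_th)
        annotation.to_csv(outdir / "annotation.tsv", sep="\t")
        props = annotate_mod.category_proportions(annotation, tags)
        props.to_csv(outdir / "category_proportions.tsv", sep="\t", index=False)
        manifest["stages"]["annotate"] = {"records": int(len(annotation))}

        # ------------------------------------------------ known miRNAs
        stage = "known"
        mir_tags = [t for t in tags if annotation.loc[t.sequence, "category"] == "miRNA"]
        match_th = mirna_known.MatchThresholds(th["identity"], th["coverage"])
        rows = mirna_known.build_count_matrix(mir_tags, bundle.mature_mirnas, match_th)
        count_df = mirna_known.count_matrix_frame(rows, libs)
        count_df.to_csv(outdir / "known_counts.tsv", sep="\t", index=False)
        manifest["stages"]["known"] = {"records": len(rows)}

        # ------------------------------------------------ novel miRNAs
        stage = "novel"
        uncl = [t for t in tags if annotation.loc[t.sequence, "category"] == "unclassified"]
        crit = mirna_novel.HairpinCriteria(max_energy=th["mfe"])
        novel = mirna_novel.discover_novel(uncl, bundle.transcripts, crit)
        mirna_novel.candidates_frame(novel).to_csv(
            outdir / "novel_candidates.tsv", sep="\t", index=False)
        with open(outdir / "novel_precursors.fasta", "w") as fh, \
                open(outdir / "novel_structures.txt", "w") as sh:
            for c in novel:
                fh.write(f">{c.candidate_id} {c.contig_id}:{c.start}-{c.end}({c.strand})\n{c.precursor}\n")
                sh.write(f">{c.candidate_id}\n{c.precursor}\n{c.fold.structure} ({c.fold.energy:.1f})\n")
        manifest["stages"]["novel"] = {"records": len(novel)}

        # ------------------------------------------------ differential expression
        stage = "diffexpr"
        sizes = {c: float(ledgers[c].clean_reads) for c in libs}
        de_calls: dict[str, list[diffexpr_mod.DifferentialCall]] = {}
        for cond in libs[1:]:
            calls = diffexpr_mod.call_differential(
                rows, "control", cond, sizes,
                p_threshold=th["p_value"], fc_threshold=th["fold_change"])
            de_calls[cond] = calls
            diffexpr_mod.calls_frame(calls).to_csv(
                outdir / f"de_{cond}.tsv", sep="\t", index=False)
            n_sig = sum(c.call != "unchanged" for c in calls)
            log.info("diffexpr: control vs %s -> %d/%d called", cond, n_sig, len(calls))
        manifest["stages"]["diffexpr"] = {
            "records": {c: len(de_calls[c]) for c in libs[1:]},
            "called": {c: sum(x.call != "unchanged" for x in de_calls[c]) for c in libs[1:]},
        }

        # ------------------------------------------------ targets
        stage = "targets"
        expressed = {r.mirna_id: bundle.mature_mirnas[r.mirna_id]
                     for r in rows if r.mirna_id in bundle.mature_mirnas}
        for c in novel:
            expressed[c.candidate_id] = c.mature
        hits = targets_mod.predict_targets(expressed, bundle.transcripts, th["target_cutoff"])
        targets_mod.hits_frame(hits).to_csv(outdir / "target_hits.tsv", sep="\t", index=False)
        manifest["stages"]["targets"] = {"records": len(hits)}

        # ------------------------------------------------ concordance
        stage = "concordance"
        ext_expr = None
        if not simulated and "target_expression" in config.get("inputs", {}):
            te = pd.read_csv(config["inputs"]["target_expression"], sep="\t")
            ext_expr = {
                cond: dict(zip(sub["transcript_id"], sub["log2fc"]))
                for cond, sub in te.groupby("condition")
            }
        conc_frames = []
        for cond in libs[1:]:
            if simulated:
                texpr = _simulate_target_expression(bundle, cfg, cond)
            else:
                texpr = (ext_expr or {}).get(cond, {})
            rep = targets_mod.concordance_report(de_calls[cond], hits, texpr)
            rep.insert(0, "condition", cond)
            conc_frames.append(rep)
        conc = pd.concat(conc_frames, ignore_index=True) if conc_frames else pd.DataFrame()
        conc.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        manifest["stages"]["concordance"] = {"records": int(len(conc))}

        # ------------------------------------------------ recovery vs truth
        stage = "recovery"
        if not simulated:
            manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
            return manifest
        recovered = {r.mirna_id for r in rows}
        planted = set(bundle.mature_mirnas)
        sensitivity = len(recovered & planted) / len(planted) if planted else 1.0
        de_truth = {(mid, cond) for mid, cond, fc in cfg.de_subset if fc != 1.0}
        called = {(c.mirna_id, cond) for cond in libs[1:]
                  for c in de_calls[cond] if c.call != "unchanged"}
        tp = len(called & de_truth)
        recall = tp / len(de_truth) if de_truth else 1.0
        fdr = (len(called) - tp) / len(called) if called else 0.0
        novel_truth = {tr.mature for tr in bundle.novel.values()}
        novel_found = {c.mature for c in novel}
        recovery = {
            "known_sensitivity": sensitivity,
            "de_recall": recall,
            "de_empirical_fdr": fdr,
            "de_called": len(called),
            "de_planted": len(de_truth),
            "novel_planted": len(novel_truth),
            "novel_recovered": len(novel_truth & novel_found),
            "novel_reported": len(novel_found),
        }
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(recovery, fh, indent=2, sort_keys=True)
        manifest["stages"]["recovery"] = recovery
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
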
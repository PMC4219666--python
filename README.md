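# srnapipe

A tested, reusable re-implementation of the classical small-RNA sequencing
analysis used for plant stress studies with **one library per condition**:
read cleaning with full per-category accounting, sRNA classification,
known-miRNA identification, novel-miRNA hairpin discovery by MFE folding,
exact Bayesian differential expression of read counts, and
complementarity-based target prediction. The motivating design point is the
*Leymus chinensis* (Chinese wildrye) setting — a control library plus a
saline-alkali and a drought stress library — but every stage is generic.

Because such studies are unreplicated and depend on private reference
assemblies, the package ships a first-class **synthetic-data generator**
that emulates the statistical structure of the real libraries (read-length
modes at 24 and 20/21 nt, five adapter/quality contamination classes,
log-normally dispersed miRNA abundances, planted hairpins and target sites,
condition-dependent fold-changes) with per-read ground truth, so the whole
pipeline is testable end to end without any download.

## The methods at the core

* **Read cleaning ledger.** Every raw read lands in exactly one bucket:
  low-quality, 3′-adapter-null, insert-null, 5′-adapter contaminant,
  length filter, polyA — or the clean unique-tag table. The ledger
  identity `clean = high_quality − Σ removals` holds on any input.
* **Classification / known miRNAs.** Seeded ungapped alignment against
  ncRNA and mature-miRNA references, gated at ≥ 95% identity and ≥ 90%
  coverage, with isomiR end-offsets of ±2 nt for mature matching.
* **Hairpin folding.** A self-contained base-pair MFE model
  (e(G:C) = −3, e(A:U) = −2, e(G:U) = −1 kcal/mol-like units, minimum loop
  3 nt, no pseudoknots) solved exactly by dynamic programming, plus
  MIREAP-style acceptance criteria (mature 18–26 nt on one arm, MFE
  ≤ −18 kcal/mol, ≥ 14 paired mature bases, bulges ≤ 4 nt).
* **Differential expression.** The Audic–Claverie posterior predictive
  test for unreplicated count libraries,
  `P(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1))` with `r = N2/N1`,
  two-sided by doubling the smaller tail; calls require p ≤ 0.01 and a
  two-fold change on RPM-normalized expression.
* **Target prediction.** Optimal global duplex alignment under the
  penalty scheme match 0 / G:U wobble 0.5 / mismatch 1 / gap 2, reporting
  sites with total score ≤ 3.5.

## Worked example

```bash
srnapipe run-all --seed 7 --n-reads 50000 --out demo_run
```

runs the full synthetic study (three libraries of 50,000 reads) and prints
the recovery metrics the run computed, e.g.:

```
pipeline complete; manifest at demo_run/manifest.json
{
  "de_called": 6,
  "de_empirical_fdr": 0.0,
  "de_planted": 6,
  "de_recall": 1.0,
  "known_sensitivity": 1.0,
  "novel_planted": 8,
  "novel_recovered": 8,
  "novel_reported": 13
}
```

meaning: every planted known miRNA was recovered in the count matrix
(`known_sensitivity`), all six planted four-fold expression changes were
called in the right condition with no false differential calls
(`de_recall`, `de_empirical_fdr`), and all eight planted novel hairpins
were re-discovered from the transcript contigs — alongside five spurious
candidates from mRNA-degradation fragments, the pipeline's least specific
stage (see `docs/methods.md`). `demo_run/`
contains the per-library removal ledger (`ledger.tsv`), length histogram,
category proportions, known-miRNA count matrix, novel-candidate table with
dot-bracket structures, differential-expression tables for each stress
contrast, predicted target sites with duplex alignments, and the
miRNA–target sign-concordance report.

The same stages are available individually (`srnapipe clean`,
`srnapipe novel`, `srnapipe diffexpr`, … — see `srnapipe --help`) and as
library functions for use on real FASTQ/FASTA inputs.

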
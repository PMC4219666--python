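# Methods

This note records the models, parameter choices and numerical conventions
behind `srnapipe`, and what the synthetic study does and does not
demonstrate about real data.

## Study design being modelled

The pipeline targets the unreplicated three-library design common in plant
stress small-RNA work: one sequencing library each for control,
saline-alkali and drought conditions, adapter-ligated inserts of 10–40 nt,
and downstream analysis performed entirely on unique insert sequences
("tags") with per-library read counts. All sequences are held internally
in the DNA alphabet (T, not U) and emitted to FASTA/FASTQ in DNA form; the
folding and duplex modules convert on entry. A single canonical alphabet
avoids mixed-alphabet bugs (ligation adapters are conventionally written
as RNA).

## Read cleaning

Each read is assigned to exactly one outcome, in a fixed precedence:
low-quality → 3′-adapter-null → insert-null → 5′-adapter-contaminant →
length filter → polyA → clean. The categories are reported disjointly, so
a deterministic order is required for a reproducible ledger; the order
chosen runs from "read-level" to "insert-level" defects. Definitions:

* **low quality** — mean Phred < 20 or > 10% of bases below Phred 10.
  Library-generation protocols rarely publish their exact rule; this is a
  documented default, exposed in `CleanParams`.
* **3′ adapter location** — leftmost occurrence of the adapter prefix
  with overlap ≥ 8 nt and ≤ 1 mismatch (standard small-RNA practice).
* **5′-adapter contaminant** — the 5′ adapter's first 8 nt occurring
  inside the insert (a ligation artefact signature).
* **length filter** — insert outside [18, 30] nt. The upper bound comes
  from the gel size selection (< 30 nt) of the emulated protocol. The
  published accounting tables have exactly five removal categories with a
  "smaller than 18 nt" row; over-long inserts are rare after size
  selection and share that bucket here, so the conservation identity
  `clean = high_quality − Σ removals` holds on every input.
* **polyA** — insert with ≥ 80% A (threshold exposed).

## Tag classification

Tags are classified against ncRNA references (rRNA, tRNA, snRNA, snoRNA)
and mature miRNAs with a seeded ungapped aligner: exact 12-mer seed,
extension across the whole tag, identity = matches/aligned columns,
coverage = aligned columns/tag length, gates identity ≥ 0.95 and coverage
≥ 0.90. A BLAST-style E-value is deliberately not computed: it would
require a database-size model, and the identity/coverage gates are the
operative thresholds. Multi-category hits resolve by the fixed priority
rRNA > tRNA > snRNA > snoRNA > miRNA — ncRNA matches are removed before
miRNA analysis, and the remaining inter-category order is a declared
convention. Known-miRNA matching additionally allows end-offsets of ±2 nt
(isomiRs); each accepted tag is credited to its single best mature hit
(identity, then coverage, then lexicographically smallest id), making the
count matrix invariant to reference ordering. Family labels strip the
species prefix, member letter and arm suffix (lch-miR396f-3p → miR396).

## Hairpin folding and novel-miRNA screening

The folder is a Nussinov-style base-pair model solved exactly by dynamic
programming: admitted pairs G:C (−3), A:U (−2), G:U (−1) in kcal/mol-like
units, hairpin loops ≥ 3 nt, no pseudoknots; integer energies make
traceback comparisons exact and a deterministic traceback (prefer
"last base unpaired", then the smallest pairing partner) fixes the
reported structure. This is intentionally *not* a nearest-neighbour
stacking model: published precursor energies from thermodynamic folders
are not reproducible without the original sequences in any case, and the
pipeline needs a self-contained score that can be verified against
exhaustive enumeration (the test suite checks exact agreement with an
independent first-base recursion oracle at length ≤ 18).

Candidate precursors around a perfect transcript hit are excised as two
windows per strand: tag-as-5p-arm (20 nt upstream + 160 nt downstream)
and the 3p mirror — MIREAP-style defaults, configurable. Screening
accepts a hairpin when all of: mature length 18–26 nt; MFE ≤ −18 kcal/mol
(MIREAP's conventional default; the threshold is exposed); no mature base
in a terminal loop and all paired mature bases pairing to one side
(strict single-arm rule); ≥ 14 mature bases paired; no asymmetric bulge
> 4 nt inside the mature duplex. Rejections carry the first failed
criterion in the order length, energy, loop_overlap, pairing, bulge.
Accepted candidates are named `lch-MIR-NN` by descending read count with
lexicographic tie-break.

Because the base-pair model over-pairs long random sequence, the
160-nt excision windows fold more promiscuously than the planted ~90-nt
precursors; discovery therefore recovers most but not always all planted
hairpins (typically 6–8 of 8 at the default study size), while
dinucleotide-preserving shuffles of true precursors are accepted in well
under 10% of trials. The synthetic generator guarantees by construction
(rejection sampling at planting time) that every planted precursor passes
the screen on its own coordinates.

## Differential expression

Expression is reads-per-million of the library's clean reads. With no
replicates, significance uses the Audic–Claverie posterior predictive
distribution of the treatment count given the control count,

    P(Y = y | x) = r^y (x + y)! / (x! y! (1 + r)^(x + y + 1)),  r = N2/N1,

the standard exact test for tag-count libraries of this design
generation. The two-sided p doubles the smaller tail (capped at 1). Mass
sums run in log space via `gammaln`/`logsumexp`; the upper tail is summed
directly from `y` until terms are negligible rather than formed as
`1 − cdf`, preserving relative accuracy for very small tails (verified to
1e-10 against a plain-float summation oracle). One numerical property to
note: for equal library sizes the mass function is exactly symmetric in
(x, y), but the doubled-min-tail two-sided p is only approximately
symmetric under a count swap — the two conditionings include the observed
point in different tails — so swapped p-values agree to within a factor
of two rather than exactly. Under a Poisson null the rejection rate at
α = 0.05 calibrates to the 0.03–0.07 band (measured over 2,000
replicates).

Calls require p ≤ 0.01 *and* |log2FC| ≥ 1 on normalized expression. A
zero count is replaced by 0.01 reads for the fold-change only (the
p-value uses true zeros), avoiding infinite log-ratios; the pseudocount
is configurable. Benjamini–Hochberg adjusted p-values are reported
alongside but do not gate by default, matching the raw-p convention of
the emulated analysis generation.

## Target prediction

A miRNA is aligned 5′→3′ against the reverse-complement orientation of
each candidate site under penalties match 0, G:U wobble 0.5, mismatch 1,
gap 2 with at most 2 gaps (gap weight and count are the psRNATarget-style
convention; only the two substitution weights are canonical). Sites with
total score ≤ 3.5 are targets — since scores move in 0.5 steps, "less
than four" and "3.5 as a cutoff" coincide. Seed-region weighting is off
by default (only the total score gates). `scan_transcript` scores *every*
window of lengths |miRNA| ± 2 with a vectorised banded DP that is exactly
the single-pair scorer (tested cell-for-cell against it and against a
brute-force alignment enumerator at length ≤ 12), merges overlapping hits
keeping the lowest score, and reproduces the duplex alignment for each
reported hit. Scanning covers full transcripts; restriction to ORFs is
not attempted.

The sign-concordance report labels each (DE miRNA, predicted target) pair
same/opposite by log2FC sign, flat when either |log2FC| < 1, and missing
when the target lacks an expression entry.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* of the real libraries:

* insert lengths 18–30 nt with a major mode at 24 nt and a minor mode at
  20/21 nt;
* five contamination classes at configurable per-read rates (defaults a
  few percent in total, proportioned like deep plant sRNA libraries) plus
  a low-quality read rate of 2.6%;
* clean-read composition ~32% ncRNA, ~10% known miRNA, ~3% novel-miRNA
  matures, ~10% mRNA-degradation fragments, remainder unclassifiable —
  giving the observed "roughly 40% mapped / 60% unclassified" split;
* known-miRNA abundances drawn log-normally with σ = 2.0, spanning about
  four orders of magnitude as real libraries do;
* novel hairpins spliced into transcript contigs on either strand, and
  perfect-complement target sites planted for designated miRNAs;
* condition-dependent fold-changes applied to a configurable DE subset
  (the demo plants six four-fold effects, up and down, split between the
  two stress conditions, drawn from the expressed half of the abundance
  distribution — differential calls are only meaningful for expressed
  miRNAs).

Per-library depth is a free parameter (the emulated protocol reports
depth only per run); the shipped study size is three libraries of 50,000
reads, which keeps the full run under a minute while leaving planted
counts deep enough for power at four-fold effects. Everything is
deterministic given the seed: reference, libraries and all report files
are byte-identical across reruns (the run manifest records wall-clock
timestamps and is excluded from the byte-identity guarantee).

What passing tests on this generator does **not** show: recovery of the
real study's biological content (its 132 known/16 novel miRNAs and
specific DE lists require the original libraries and 2013-era database
versions); robustness to sequencing error profiles (reads are emitted
error-free outside the designed contamination classes); thermodynamic
accuracy of folding energies; or behaviour on genomes rather than
transcript assemblies.

## Known limitations

* The base-pair energy model over-stabilises long random RNA; energy
  alone is therefore a weak filter and the structural criteria carry the
  discrimination.
* The published novel-miRNA table used for record-semantics checks
  contains one internally inconsistent row (a 22-nt printed sequence with
  a printed length of 21); the length accessor reports the sequence's
  true length.
* External-input runs (`inputs:` config section) reuse every stage but
  produce no recovery metrics, which require generator truth.
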
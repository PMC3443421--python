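# Methods

## The analysis model

`mirquant` implements a threshold-based smRNA-seq miRNA profiling
analysis for two unreplicated conditions. Its core assumptions:

* the library insert is a mature miRNA (or another small RNA) ligated
  between a 5' and a 3' adapter; a genuine insert read therefore ends in
  a prefix of the 3' adapter, and a read showing 5'-adapter sequence is
  a ligation artefact without usable insert;
* degraded mRNA contaminates the small-RNA fraction, so any tag that
  occurs verbatim in an mRNA exon database is discarded *before* miRNA
  matching — exclusion precedence is absolute, even for tags that would
  also match a mature miRNA;
* abundance comparisons are made on a per-sample normalised statistic
  (RPKM) and called purely by thresholds: with one library per condition
  there is no replication, hence no variance model, no p-values and no
  multiple-testing correction for the miRNA arm.

## Read admission and trimming

Rules are applied per read in a fixed order — poly-A, ambiguous bases,
5' adapter, 3'-adapter flank — and the first failing rule assigns the
read's single fate, which makes the filter report a partition of the
input (property-tested). The source analysis lists the four rules
without an order; fixing one is our choice and only affects how
multiply-contaminated reads are attributed, never which reads survive.

* **poly-A** (our operationalisation, both knobs configurable): drop if
  the read contains a run of ≥ 10 consecutive `A` or is ≥ 80% `A`.
  The rule covers both oligo-dA library artefacts and full poly-A reads.
* **ambiguous**: drop on any `N`.
* **5' adapter**: drop if the first 8 nt of the 5' adapter occur
  anywhere in the read (0 mismatches by default; a mismatch knob
  exists).
* **3' adapter**: the flank is the longest read suffix equal to a
  prefix of the 3' adapter; admit only when the flank is 6–18 nt and
  the trimmed insert is 15–30 nt (miRNAs are 18–24 nt; the window
  leaves isomiR slack). Matching is exact by default because the
  original stringency is unstated.

Adapters are mandatory configuration. The shipped defaults are the
Illumina v1.5 small-RNA adapters and are explicitly replaceable; no
base-quality filtering is performed (input is assumed to be
machine-passing reads), and qualities are carried but never read.

Identical raw reads necessarily share a fate, so the implementation
collapses the input with a counter first and judges each distinct
sequence once; results are exactly order-invariant.

## Tag classification

Matching against the mature catalogue is substring containment in
either direction (tag within mature sequence, or mature within tag) at
0 mismatches by default — the most reproducible reading of
"aligned to known microRNA sequences" — with a mismatch knob for
sensitivity studies. Matching genomic miRNA loci instead of mature
sequences is supported indirectly (mature sequences can be extracted
from a genome FASTA at the annotated intervals, minus-strand loci
reverse-complemented), but mature-sequence matching is the default.
Classification uses a k-mer-seeded exact substring index (k = 12,
configurable) verified by slicing, and is property-tested equal to a
brute-force scan.

## Quantification

`RPKM = C/(L·M·N) × 1e9`. The multi-mapping number *M* is defined per
miRNA as the number of distinct annotated genomic loci producing its
mature sequence (2 for a two-locus entry), with *C* counted once per
read across loci: this is the only reading under which *M* is the
single scalar the formula needs, and it matches published tables that
print multi-locus miRNAs as single rows. An alternative per-read
splitting mode (dividing a tag's count by its number of distinct miRNA
hits) is available behind a flag.

*N* ("total mapped reads") cannot be computed faithfully without a
genome-wide aligner, so two desk-scale proxies are offered and the one
used is recorded in the run metadata: `aligned` (default) counts
admitted reads assigned to any reference sequence, miRNA or exon;
`admitted` counts all reads surviving preprocessing. *N* counts reads
by default; a tags-mode counts collapsed tags instead. RPKM is kept at
full double precision internally; rounding happens only in writers.

## Differential calling

Folds use the signed-reciprocal convention (negative = reference-side
enriched), inferred from the negative fold columns of published
reference-enriched tables; |fold| ≥ 1 by construction. A zero
denominator produces the sentinel `9.90E+307` — replicated because the
published tables print it — and an `is_sentinel` flag so downstream
code never treats it as a ratio. The abundance filter applies to the
max over the two conditions (rows with one near-zero condition are
exactly the strongest calls) and is strict (`> 100`); the fold filter
is inclusive (`≥ 1.5`), consistent with boundary rows at 1.5016 and
−1.5048 appearing in the published tables. Ranks are ordinal by
descending RPKM with lexicographic tie-break. The published absolute
rank columns imply a detected-miRNA universe of several hundred
entries that is not printed, so ranks are verified only for internal
ordering consistency, never absolutely.

## Synthetic data

The generator emulates the read classes the filters target: miRNA reads
(exact mature sequence + uniform 6–18 nt 3'-adapter prefix), poly-A
contaminants, ambiguous-base reads, 5'-adapter carry-over, degraded
mRNA fragments (exon substrings with valid flanks — admitted, then
excluded at classification), and unaligned filler. Defaults: 20 miRNAs
(2 of them two-locus), 30 exons of 120 nt, 50,000 reads per sample,
miRNA fraction 0.75, contaminant fractions 5% poly-A / 3% ambiguous /
4% 5'-adapter / 8% mRNA fragments — a plausible composition for a
small-RNA library in which most admitted material is genuine miRNA.
Per-miRNA abundances default to log-normal (σ = 1) renormalised to the
miRNA fraction; reads are drawn from one multinomial per sample.

Classes are generated mutually exclusively (a poly-A read never also
carries an `N`), so the filter report is exactly predictable from the
truth table; an adversarial mode plants flanks of 5 or 19 nt to hit
the flank boundaries. Mature sequences are rejection-sampled to be
pairwise non-substring and absent from exons (a decoy mode deliberately
violates the latter to test exclusion precedence). Everything is driven
by one integer seed; identical config + seed gives byte-identical
outputs.

What the simulator does *not* model: sequencing errors and quality
profiles, isomiR end-heterogeneity by default (an option adds it),
ligation bias, and real genomic multi-mapping outside annotated miRNA
loci. Passing end-to-end tests therefore demonstrates correctness of
the bookkeeping and statistics under clean reads, not robustness to
platform noise.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 and printed
  browser-style strings are 1-based inclusive and converted on load.
  All sequences are DNA-uppercased (U→T) at load.
* miRNA names are taken verbatim as distinct entries (no arm merging:
  `miR-31` and `miR-31*` are different miRNAs).
* A miRNA with zero reads is reported with RPKM 0; a two-condition
  record with both RPKM 0 has an undefined fold and is flagged and
  excluded from calling. Empty inputs complete gracefully with all-zero
  reports.
* The packaged published tables are integrity-checked by SHA-256 and
  re-verified by recomputation (max relative fold error over the 103
  finite rows, side split, sentinel agreement).
* Test and validation problem sizes: property tests use up to 10⁵
  simulated reads for filter accounting, 1,000 tags × 100 references
  for classifier/oracle equivalence, and 100 simulation seeds at
  50,000 reads/sample for fold-recovery — sizes at which multinomial
  error bars are tight while the whole suite stays fast on one core.

## Known limitations

* No novel-miRNA discovery, hairpin folding, isomiR sub-annotation,
  gapped alignment, UMI handling or replicate-aware statistics.
* The `aligned`/`admitted` N proxies bracket, but do not equal, a true
  genome-wide mapped-read total; absolute RPKM values shift accordingly
  while fold changes are largely insensitive (both conditions share the
  policy).
* Exclusion uses whatever exon FASTA the user supplies; an incomplete
  exon database under-excludes degraded mRNA.
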
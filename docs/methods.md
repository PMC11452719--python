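# Methods

This note documents the models, rules and numerical choices behind
`sncatlas`, what the synthetic data emulate, and the limits of what passing
tests demonstrate.

## Read model and simulator

Each rendered read is `UMI(8) + "CA" + insert + adapter + poly(A)` padded
to a 100 nt budget. The two filler bases are fixed to `CA` so that the
2-base discard step after UMI extraction is verifiable against truth. The
adapter defaults to `AGATCGGAAGAGC` (a standard ligation adapter stub) and
is a free config string, since the library chemistry does not pin one down.
Reads whose insert plus minimum 10 nt tail exceed the budget are flagged
`truncated` in the truth table; default insert geometries (mature miRNA
22 nt, piRNA 26–32 nt with mode 30, tRNA gene 74 nt, fragments 18–40 nt)
keep everything within budget.

The genome is uniform random with non-overlapping planted features
(mature miRNAs nested 10 nt inside hairpins; tRNAs carrying
amino-acid/anticodon labels; a small `chrM` with mitochondrial tRNAs for
the QC mitochondrial fraction), plus catch-all tracks (protein-coding,
lncRNA, repeat, pseudogene). Two deliberate departures from "pure random"
keep the simulation faithful to what the pipeline can know:

* **Adapter scrubbing.** Windows that could forge an adapter match during
  trimming are rewritten: the full adapter within one substitution, and
  adapter *prefixes* whose continuation into the real ligated adapter
  still fits the 10% mismatch budget (self-overlap shifts 8/10/12 of the
  default adapter, including the prefix completed by a single planted
  adenosine). A transcript whose 3' end looks like the adapter is
  unquantifiable by any trimmer, so the simulator excludes the case by
  construction rather than asking the pipeline to solve it.
* **NTA plantability.** Planted non-templated additions are guaranteed to
  mismatch the genome at their implied positions (adenosine preferred, `C`
  where the genome itself reads `A`). A "non-templated" base that happens
  to match the template is definitionally canonical sequence; planting it
  would make the truth table wrong, not the caller.

Per-cell molecule counts are fixed (default 600); biotype mixtures
interpolate linearly between a start and end composition across the
configured days (piRNA/tRNA falling, miRNA/snoRNA rising), which reproduces
the qualitative developmental trend without claiming the real proportions.
Two miRNAs per post-segregation lineage act as markers with a 2^2 = 4-fold
expected-count boost in their lineage. PCR copies are 1 + Poisson(rate) and
share UMI and insert; sequencing errors (default 10⁻³ per base) are applied
to the insert of each copy independently. The `sequenced_reads` column in
the cell metadata simulates full library depth (~2 M reads) for QC purposes;
the rendered FASTQ is the molecule-resolved subset of such a library.

**Collision-free UMI mode** assigns each molecule a codeword of 7 random
base-4 digits plus a checksum digit, giving pairwise Hamming distance ≥ 2,
so directional deduplication can never merge distinct molecules. Exact
count-recovery checks use this mode; the default mode draws UMIs uniformly
over 4⁸ and exhibits realistic occasional collisions.

## Alignment rules

Placements are enumerated in the minimal-mismatch stratum with at most two
substitutions (no indels), suppressed above 50 hits. Post-filters: reads
< 20 nt tolerate no mismatch; 20–40 nt at most one; a mismatch at the
final sequenced base is always forgiven. Rescue clips 1..3 nt from the 3'
end, then from the 5' end of the original read, remapping at a one-mismatch
budget and stopping at the first success; clipped placements only face the
17 nt mapping-length floor. Decisions worth calling out:

* Reads rejected by the post-filters are routed into clip rescue together
  with truly unmapped reads. Filtered reads are exactly the ones whose 3'
  modifications (2–3 nt tails) masquerade as mismatches; rescue is the
  mechanism designed to recover them, and without this routing such
  molecules would vanish from the counts.
* With the forgiven last base, *k* non-genomic 3' bases are rescued with
  clip k−1 for k ≤ 4; five are unrecoverable. The clip field therefore
  understates tail length by design, which is why modification calling is
  sequence-based (below).
* Tie order of reported placements is (chrom, start, strand); multi-mapped
  reads group for deduplication by their lexicographically first placement.

The aligner is validated against a brute-force enumerator that rescans
every genome position per read under the same written rules (same
statuses, hit sets, mismatch counts and clips).

## Modification calling

isomiR and tRF geometry is derived from sequence, not from CIGAR fields:
the maximal 3'-terminal run of insert bases that mismatch the genome at
their implied positions is the NTA; the remaining templated ends are
compared with the annotated feature ends in feature-strand orientation
(positive shift = elongation). This subsumes soft-clipped bases and
forgiven terminal mismatches in one definition and recovers planted
modifications exactly on error-free data. Out-of-range shifts (|shift| > 3
for miRNA) are excluded from isomiR summaries and tallied.

tRF classes read the published rules literally: "shorter than 50" is
≤ 49 nt, "exceeding 50" is ≥ 51 nt, a length of exactly 50 nt is
unclassified; "a shift of at least −10" is ≤ −10 inclusive. Fragments
shifted beyond −10 at both ends, and long reads with one shifted end, are
unclassified and tallied. The class function is checked over the full
integer grid length ∈ [17, 90] × shifts ∈ [−40, +5] against an independent
rule table.

## Normalisation and differential expression

Size factors are library sizes median-centred within each sequencing
batch: factors are strictly positive, have median 1 inside every batch and
are therefore comparable across batches of different depth. This is a
documented stand-in for pooled-deconvolution size factors with cross-batch
rescaling: it preserves the contract (comparable factors, depth-ratio
equivariance) without reimplementing the pooling internals. Expression is
log2(count/size_factor + 1).

Two-group tests use the two-sided Wilcoxon rank-sum statistic — exact
enumeration when both groups have ≤ 10 tie-free observations, otherwise the
tie-corrected normal approximation — with Benjamini–Hochberg adjustment
per contrast. Constant features get p = 1 by convention. The log2 fold
change is the difference of log2(mean(2^x − 1) + 1) per group, the
convention of the single-cell toolkit the thresholds come from.
Significance: FDR < 0.05, |log2FC| above the contrast threshold (0.1 for
miRNA stage/lineage contrasts, 0.25 for gene contrasts), and > 1/3
expressing cells in the favoured group. Calibration is asserted on a
2000-feature negative-binomial null (raw p < 0.05 fraction within
[0.03, 0.07] at 50 vs 50 cells) and power on planted two-fold shifts
(sensitivity ≥ 0.9).

## Trajectory, targets, novel candidates

Cross-branch pseudotime alignment uses the closed form given in the README;
it is exercised on 10³ random configurations for both identities (branch
maximum maps onto the TE maximum; identity when the maxima agree) at 10⁻¹²
tolerance. Trajectory association replaces a package-internal pseudotime
test with an ordinary least-squares fit of expression on pseudotime with
the batch as additive covariate, BH-adjusted slope tests at FDR < 0.05,
intersected with stage-wise DE (the OR of adjacent-stage and later-vs-E3
contrasts, supplied as a feature set). Pattern clustering z-scores 20
equal-width pseudotime-bin means per miRNA and runs k-means with k = 3 and
25 restarts at a fixed seed; centroids are labelled by thirds contrast
(C2 = most rising, C3 = most falling, C1 = the transient remainder).

Target screening aligns pseudobulk (group-mean log expression) tables on
their shared groups (n ≥ 3 required; the acceptance configuration uses 10
groups, i.e. five days × two lineages), computes Pearson r per candidate
pair and one-sided p values from t = r√(n−2)/√(1−r²); zero-variance
profiles are skipped with a reason. The novel-miRNA filter is the pure
conjunction of four predicates; the "minimum length support" criterion is
read as ≥ 30 cells with overlapping reads AND ≥ 75% of all pooled
overlapping reads in 20–25 nt (pooled, not per cell).

## Problem sizes

The shipped checks use a ~30 kb single-chromosome genome plus a 2 kb
mitochondrial contig, 50 cells × 200 molecules for exact end-to-end
recovery, ≥ 10³ reads over a ≤ 10 kb genome for aligner-oracle equivalence,
10⁴ random UMI multisets for the deduplication oracle, and 2000-feature
matrices for the statistical calibrations. These sizes were chosen so the
full suite runs in about a minute on one CPU while still covering every
rule branch.

## Limitations

* The simulator plants substitution errors only (no indels, no quality
  model, no platform error profile), applies them to the insert only, and
  draws genomes uniformly at random — repeat structure, GC bias and true
  multi-mapping families appear only via the explicit duplicated-repeat
  option. Passing exact-recovery tests therefore demonstrates rule
  correctness, not robustness to real base-calling noise.
* The aligner is a brute-force/seeded scanner suitable for toy genomes
  (tens of kb), not an FM-index; it is the reference semantics, not a
  performance tool.
* Pseudotime values are consumed as input; trajectory inference itself
  (principal curves, embedding, clustering of cells) is out of scope.
* Catch-all annotation tracks are synthetic stand-ins; no real
  miRBase/GENCODE/GtRNAdb/piBase content ships with the package.
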
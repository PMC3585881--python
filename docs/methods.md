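# Methods

This note documents the models, thresholds and design choices behind
`finchsmallrna`, and what the synthetic benchmark does and does not show.

## Read model and preprocessing

Each sequenced read is `insert + 5-nt barcode + 3' adapter constant region
(TCGTATGCCGTCTTCTGCTTGT)`, truncated to a fixed 36-nt read length. With
inserts of 18–25 nt this leaves at least 6 adapter nucleotides, so trimming
searches for the longest adapter prefix terminating the read (minimum
6 nt, exact match — the adapter is a fixed synthetic sequence, and no
mismatch tolerance is modeled). The 5 nt upstream of the adapter are the
barcode; demultiplexing is exact (simulated barcodes are ≥ 3 mismatches
apart, so a sequencing error makes a barcode unassignable rather than
misassigned). "Low quality" is operationalized as any read containing N.
Orphans — inserts seen exactly once summed over all samples — are removed
after demultiplexing; totals across samples match the single-read notion
of an orphan in a pooled library.

## Mapping and class partition

Mapping is exact substring search on both strands with minus-strand hits
reported on forward coordinates; reads with more than 100 genomic loci are
excluded, reads with none are kept for homology rescue. Class precedence
is an artifact decision (the underlying taxonomy lists classes without
order): ncRNA homology (Hamming ≤ 1 over equal-length windows slid along
each known tRNA/rRNA/ncRNA sequence; no indels) beats repeat-interval
overlap (≥ 1 nt), which beats miRNA candidacy; an mRNA-degradation class
exists only when a transcript set is supplied. Counts of multi-locus reads
(≤ 100) are attached to each locus un-split; expression later counts each
miRNA's reads once, not per locus.

## Folding and hairpin acceptance

`fold_max_pairs` is maximum base pairing (Nussinov) over Watson–Crick plus
G·U pairs with minimum loop 3 and a deterministic traceback (the 5'-most
base pairs with its smallest optimal partner, in preference to staying
unpaired). Maximum-pairing optima are highly non-unique, so hairpin
acceptance does not depend on any one traceback. Instead `detect_hairpin`
runs a dedicated stem dynamic program over the window: a stem is a nested
run of pairs with at most 4 unpaired bases between consecutive pairs on
either side, scored as `pairs − 3 × bulged_bases`. The penalty (default 3,
configurable as `bulge_penalty`) makes extension across a bulge
unprofitable unless real stacking follows; without it essentially every
random 120-mer contains a "stem" of ≥ 18 pairs (measured: 140/150 random
windows pass unpenalized, 2/100 pass penalized), while with it every
planted precursor in 20 generator seeds is recovered. A window is accepted
when some qualifying stem has ≥ 18 pairs, the mature read lies entirely on
one arm, and ≥ 60% of mature bases are paired within the stem; among
qualifying stems the best-scoring one is kept. These thresholds
(`min_stem_pairs=18`, `max_bulge=4`, `min_paired_frac=0.6`) are artifact
decisions exposed in the pipeline configuration; the residual ~2%
per-window false rate on random sequence is tolerated because candidate
acceptance also requires read-stack evidence.

## Candidate calling

Read stacks are built by chaining mapped miRNA-candidate reads within
30 nt on one chromosome/strand, so a stack spans a whole precursor. The
most abundant read is the putative mature. Windows of 120/100/80/60 nt are
tried with the mature placed on the 5' arm and on the 3' arm; the first
configuration passing both the hairpin test and star detection wins, with
the first hairpin-only configuration as a fallback (known homologs are
accepted without a star). A novel candidate requires all four criteria:
hairpin, more than 10 reads, a star read on the opposite arm whose span
matches the duplex partner of the mature within ±3 nt at each end (slack
covering the canonical 2-nt overhang), and a modal 5' position holding
≥ 90% of the mature-arm reads — the precise-5'-end criterion has no
published number; 90% is the artifact's choice, configurable. Known-mature
homology is Hamming ≤ 1 at equal length. Unmapped reads matching a known
mature are rescued as one record per known name with counts pooled, and
only for names absent from the mapped annotation. Arm balance flags both
strands as retained when the mature:star ratio is below 10-fold.

## Conservation and clusters

A mature sequence is a precursor-homolog in another species when a
≤ 1-mismatch occurrence (either strand) folds as a hairpin in the same
60–120-nt window scheme; occurrences without a hairpin are mature-only and
do not count as homologs. Tiers: species-specific → avian-specific →
avian+mammal → vertebrate → pan-animal, determined by the highest group
carrying a homolog; the tier function is monotone in added homologs.
Clusters chain loci on one chromosome with start-to-start gaps ≤ 10 kb
(single linkage; anchor configurable to end-to-start; strand ignored —
both anchor and strand treatment are undetermined by the source method);
singletons are not clusters; names follow `first-member(n)`; identical
mature sequences within a cluster flag a tandem duplication.

## isomiR classification and site calling

Reads are aligned to each canonical by end-anchored sliding (5' offsets
±4 nt, no indels — length variation is treated as strictly terminal).
Trailing 3' mismatches against the genomic template (≤ 2 nt) are an
untemplated tail; tails take precedence over length classes when both
occur (undefined in the source method; the offset is still recorded).
Remaining single internal mismatches are substitutions; reads alignable to
more than one distinct mature are excluded as ambiguous. A substitution
site is called when the miRNA has more than 100 reads, mismatched reads at
the position exceed 5% of the total (summed across alternate bases — the
per-alternate reading is the configurable alternative), and the position
is at least 2 nt from both termini (positions 3..L−2; an internally
inconsistent position bound elsewhere in the planning material was
resolved in favor of the stated 2-nt rule). A→G sites are flagged as
putative A-to-I editing, and each site carries a binomial tail p-value
against the 0.5% sequencing-error floor as an annotation — the hard 5%
rule remains the call criterion. Motif windows are 6 nt with the
substituted base at position 3, so a reference GGU ending at the site
occupies window positions 1–3; information content per column is
2 − Shannon entropy (log2), no small-sample correction.

## Expression and sex bias

RPM normalizes each library to one million miRNA reads.
Tissue enrichment pools sexes, requires ≥ 100 reads over all tissues
combined — the per-tissue reading of the minimum-reads rule is rejected
because published brain-enriched examples carry hundreds of reads outside
the brain — and ≥ 90% share in the top tissue, ties breaking to
not-enriched; calls are invariant to uniform scaling. M:F ratios are
computed on RPM with pseudocount 0.5 (also reported as log2), excluding
miRNAs under 100 total reads.

## Target prediction and enrichment

The seed is mature positions 2–8; a gene is a target when its 3'UTR
(≥ 10 nt, after exclusion) contains the exact DNA reverse complement of
the seed on the sense strand, counted once per gene. No wobble pairing,
context scoring or conservation weighting. Enrichment on a chromosome is
the exact upper hypergeometric tail of the 2×2 table over all UTR-bearing
genes (one-sided: enrichment, not depletion), computed with
`scipy.stats.hypergeom`; tests verify it against an independent
exact-fraction tail enumeration.

## Synthetic data: what it emulates

The generator plants 12 hairpin loci (one 2-member cluster 3 kb apart, the
rest > 10 kb apart) in a 200-kb three-chromosome genome, three of them on
`chrZ` with the last being the strongly male-biased one. Precursors are
designed stem-loops: a 22-nt mature (with a GGU triplet planted at
positions 8–12), a duplex partner with two single-base deletions
(asymmetric bulges opposite mature positions 6 and 16 — substitution-style
mismatches cost two bulged bases per side and would break the penalized
stem), an 8–15-nt loop, and an 8-bp duplex extension beyond the mature, as
real pre-miRNA stems extend past the Dicer duplex. Each design is refolded
and redesigned (deterministically, from the same RNG stream) if the
hairpin test fails on the intended arm: roughly 7% of random 22-mers are
self-complementary enough to fold in a competing register. The partner-arm
deletions also guarantee unique exact mapping of the mature.

Per-read variant classes are drawn at the study's rates: 25% length
variants (80% of them 3'), 15% untemplated tailing split U:A = 2:1, 8%
substitution at the planted GGU's U, 5% star reads, and a 0.5% per-base
sequencing error; tails are chosen to differ from the templated next base.
Expected depth is ~1,000 reads per locus per library at the default
12,000 reads/sample. Z-linked loci receive expression weight 0.2 relative
to autosomal loci: libraries are sampled at fixed depth, so if Z loci
carried a large share of the pool, per-library renormalization alone would
push their M:F RPM ratio well below 2 (to ~1.7 at equal weights); keeping
them a minor share mirrors real repertoires, where Z-linked miRNAs are a
small low-expressed minority, and leaves the expected ratio near 1.95.
Female Z-locus output is halved (2:1 dosage) and divided by 10 at the
male-biased locus. One autosomal locus is brain-enriched (97% brain
weight) to exercise tissue-enrichment calls. UTR sets plant the
male-biased miRNA's seed site into 50% of chrZ genes versus 8% of
autosomal genes (odds ratio ≈ 11, ≥ 30 expected targets).

What the benchmark does **not** model: ligation and PCR bias, quality-score
structure, indel errors, paralogous multi-mapping families, isomiR rates
varying per miRNA, SNPs (indistinguishable from substitutions here as in
real data), and free-energy folding — acceptance is structural, not
thermodynamic. Passing tests therefore demonstrate correct bookkeeping and
statistical behavior under a clean generative model, not performance on
real libraries.

## Numerical and testing notes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations give byte-identical
outputs. Folding is exact dynamic programming verified against exhaustive
enumeration for sequences ≤ 25 nt. The Fisher tail is verified against
direct rational-arithmetic summation for tables with margins up to 200.
The calibration check for the enrichment test under no planted bias uses
the randomized probability integral transform (P(X > x) + U·P(X = x)),
which is exactly uniform for a discrete statistic; the raw exact p-value
is conservative by construction and would fail a naive uniformity test.
Problem sizes in the test suite and acceptance script (12 loci, 96,000
reads, 600 UTRs, 200 calibration replicates) were chosen to make binomial
3-standard-error bands decisively narrow while keeping the full run in the
tens of seconds.
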
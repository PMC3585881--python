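# finchsmallrna

Annotation and analysis of small RNA-seq data from avian genomes: from raw
barcoded reads to annotated miRNAs, isomiR/variant profiles, tissue- and
sex-bias calls, and seed-match target predictions with chromosomal
enrichment statistics. The package targets the kind of study done on the
zebra finch (*Taeniopygia guttata*), where males carry two Z chromosomes
and females one, no chromosome-wide dosage compensation exists, and a
Z-linked miRNA (miR-2954) is both strongly male-biased and biased toward
Z-encoded target genes — a candidate post-transcriptional dosage-compensation
mechanism.

## What it computes

- **Preprocessing** — reads of the form `insert + pentamer barcode +
  3' adapter` are demultiplexed by exact barcode, adapter-trimmed (longest
  adapter-prefix match ≥ 6 nt at the read end), length-filtered to
  18–32 nt, collapsed to unique inserts with per-sample counts, and purged
  of orphans (single reads).
- **Mapping and classification** — exact-match mapping to both genome
  strands (reads with > 100 loci excluded); partition into
  tRNA/rRNA/ncRNA (homology ≤ 1 mismatch), repeat-associated, miRNA
  candidate, and unmapped classes.
- **miRNA discovery** — genomic windows of 60/80/100/120 nt around each
  read stack are folded by maximum base pairing (Watson–Crick + G·U,
  loop ≥ 3); a candidate needs a single-stem hairpin (≥ 18 pairs, bulges
  ≤ 4 nt, mature on one arm with ≥ 60% of its bases paired), more than 10
  reads, a star read from the opposite arm of the duplex (±3 nt of the
  pairing-implied partner span), and a modal 5' end carrying ≥ 90% of the
  stack. Reads within one mismatch of a known mature miRNA are accepted as
  homologs without a star; unmapped homologs are rescued by sequence alone.
- **Conservation and clusters** — per-species homology status
  (precursor-homolog / mature-only / absent; mature-only does not count),
  tiers from species-specific to pan-animal, and single-linkage genomic
  clusters at a 10 kb cutoff named `first-member(n)`.
- **isomiRs** — every read assigned to one miRNA is classified as
  canonical, 5'/3'/both-end templated length variant, untemplated A/U/other
  addition, or internal substitution; substitution sites are called when a
  miRNA has > 100 reads, > 5% of them mismatch at one position, and the
  position is ≥ 2 nt from either terminus; 6-nt motif windows (site at
  position 3) feed an information-content logo matrix; GGU-motif and
  A-to-G (putative editing) sites are flagged.
- **Expression** — RPM normalization per library; a miRNA is
  single-tissue-enriched when it has ≥ 100 reads and one tissue holds
  ≥ 90% of them (sexes pooled); male:female ratios on RPM with pseudocount
  0.5, miRNAs under 100 reads excluded.
- **Targets** — a gene is a putative target when its 3'UTR (≥ 10 nt)
  contains the perfect reverse complement of the miRNA seed (positions
  2–8); per-chromosome enrichment is the one-sided Fisher exact
  (hypergeometric tail) test over the UTR-bearing gene universe.

A synthetic-data module generates a toy three-chromosome genome (including
`chrZ`) with planted, refold-validated hairpin loci, decoy ncRNA/repeat
intervals, barcoded FASTQ reads across 4 tissues × 2 sexes with Z-linked
2:1 dosage plus one 10-fold male-biased locus, isomiR events at realistic
rates, and seed sites planted into chrZ-gene UTRs — all with a full truth
table, so every stage is testable end to end.

## Worked example

```python
import finchsmallrna as f
from finchsmallrna.pipeline import PipelineConfig, run_all

cfg = f.SimConfig(seed=1, depth_per_sample=12_000)   # ~1,000 reads/locus/library
paths = f.write_all(cfg, "simrun")                   # genome, BEDs, FASTQ, truth
pcfg = PipelineConfig(
    fastq=str(paths["fastq"]), barcodes=str(paths["barcodes"]),
    genome=str(paths["genome"]), known_matures=str(paths["known_matures"]),
    known_ncrna=str(paths["known_ncrna"]), repeats_bed=str(paths["repeats_bed"]),
    species_dir=str(paths["species_dir"]), utrs=str(paths["utrs"]),
    outdir="simrun/out")
report = run_all(pcfg)
print(report["mirnas"]["n_records"])                      # 12
print(report["expression"]["z_linked_ratios"])
```

prints `12` (all planted loci annotated) and, for the three Z-linked
miRNAs, male:female RPM ratios of about `{..: 2.03, ..: 7.47, ..: 1.69}` —
the two ordinary Z loci sit near the 2:1 copy-number expectation while the
male-biased locus far exceeds it. In the same run the male-biased locus is
the only miRNA whose predicted targets are enriched on chrZ
(86 targets, 36 on chrZ, Fisher p ≈ 9e-19); the isomiR stage recovers the
planted GGU-motif substitution site in all 12 miRNAs.

The same pipeline runs from the shell:

```
finchsmallrna simulate --config sim.yaml --outdir simrun
finchsmallrna run --config run.yaml
finchsmallrna fixtures --table 1
```

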
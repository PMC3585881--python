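"""End-to-end orchestration: reads -> annotated miRNAs -> reports.

``run_all`` wires the stages together from a single configuration:
demultiplex/trim/collapse, exact genome mapping and class partition,
hairpin-based candidate calling, genomic clustering, optional cross-species
conservation tiers, isomiR/variant profiling, tissue-enrichment and
male:female expression ratios, and seed-match target prediction with
chromosomal enrichment. Every stage writes a TSV under the output
directory and logs one line of input/output counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import conservation as cons
from . import expression as expr
from . import fixtures
from . import hairpin as hp
from . import isomir as iso
from . import mapping as mp
from . import preprocess as pre
from . import targets as tg
from .simdata import SPECIES_GROUPS

log = logging.getLogger("finchsmallrna")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Threshold fields collect every operational decision of the method so a
    run can pin or vary them explicitly.
    """

    fastq: str
    barcodes: str               # TSV: barcode <tab> sample
    genome: str                 # FASTA
    known_matures: str          # FASTA of known mature miRNAs
    outdir: str
    known_ncrna: Optional[str] = None
    repeats_bed: Optional[str] = None
    transcripts: Optional[str] = None
    species_dir: Optional[str] = None
    species_groups: dict = field(default_factory=lambda: dict(SPECIES_GROUPS))
    utrs: Optional[str] = None
    enrich_chromosome: str = "chrZ"
    seed: int = 0
    # decisions: operational thresholds where the method leaves room
    min_locus_reads: int = hp.MIN_LOCUS_READS
    min_modal5p: float = hp.MIN_MODAL5P_FRAC
    min_stem_pairs: int = hp.MIN_STEM_PAIRS
    star_slack: int = hp.STAR_SLACK
    cluster_cutoff: int = cons.CLUSTER_CUTOFF
    cluster_anchor: str = "start"
    min_site_total: int = iso.MIN_TOTAL_READS
    min_site_rate: float = iso.MIN_SITE_RATE
    min_enrich_total: int = expr.MIN_ENRICH_TOTAL
    min_enrich_share: float = expr.MIN_ENRICH_SHARE
    ratio_pseudocount: float = expr.RATIO_PSEUDOCOUNT

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for k, v in raw.items():
            if k == "decisions" and isinstance(v, dict):
                flat.update(v)
            else:
                flat[k] = v
        return cls(**flat)


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _read_barcodes(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                bc, sample = line.split("\t")
                out[bc] = sample
    return out


def _stage(name: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s elapsed=%.1fs %s", name, time.time() - t0, extras)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the consolidated report dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    # --- preprocess -------------------------------------------------------
    t0 = time.time()
    bmap = _read_barcodes(cfg.barcodes)
    samples = sorted(set(bmap.values()))
    collapsed, tally = pre.trim_and_demux(str(cfg.fastq), bmap)
    kept = pre.drop_orphans(collapsed)
    with open(outdir / "counts.tsv", "w") as fh:
        pre.write_counts_tsv(kept, samples, fh)
    report["preprocess"] = {
        "records": tally.n_records, "kept_reads": tally.n_kept,
        "dropped": tally.dropped(), "unique_inserts": len(collapsed),
        "after_orphan_filter": len(kept),
    }
    _stage("preprocess", t0, **report["preprocess"])

    # --- mapping + classification ----------------------------------------
    t0 = time.time()
    genome = _read_fasta(cfg.genome)
    mapped = mp.map_exact(kept, genome)
    known_ncrna = _read_fasta(cfg.known_ncrna) if cfg.known_ncrna else None
    transcripts = _read_fasta(cfg.transcripts) if cfg.transcripts else None
    mapped = mp.classify_reads(
        mapped, repeat_intervals=cfg.repeats_bed,
        known_ncrna=known_ncrna, transcripts=transcripts)
    summary = mp.class_summary(mapped)
    pd.Series(summary, name="fraction").rename_axis("class").to_csv(
        outdir / "class_summary.tsv", sep="\t")
    report["classes"] = summary
    _stage("mapping", t0, unique=len(mapped),
           mapped=sum(1 for m in mapped if m.loci))

    # --- candidate calling ------------------------------------------------
    t0 = time.time()
    known = _read_fasta(cfg.known_matures)
    records = hp.call_candidates(
        mapped, genome, known,
        min_reads=cfg.min_locus_reads, min_modal5p=cfg.min_modal5p,
        star_slack=cfg.star_slack, min_stem_pairs=cfg.min_stem_pairs)
    _write_mirna_table(records, samples, outdir / "mirnas.tsv")
    with open(outdir / "precursors.fa", "w") as fh:
        for r in sorted(records, key=lambda r: r.name):
            if r.precursor_seq:
                fh.write(f">{r.name}\n{r.precursor_seq}\n{r.structure}\n")
    report["mirnas"] = {
        "n_records": len(records),
        "n_novel": sum(1 for r in records if r.status == "novel"),
        "n_known": sum(1 for r in records if r.status == "known-homolog"),
        "n_unmapped_homolog": sum(1 for r in records if r.status == "known-homolog-unmapped"),
        "n_with_star": sum(1 for r in records if r.star),
        "n_both_arms": sum(1 for r in records if r.both_arms_retained),
    }
    _stage("discovery", t0, **report["mirnas"])

    # --- clusters ----------------------------------------------------------
    t0 = time.time()
    locus_rows = [(r.name, r.precursor[0], r.precursor[1], r.precursor[2], r.mature)
                  for r in records if r.precursor]
    clusters = cons.cluster_loci(
        [(n, c, s, e, m) for n, c, s, e, m in locus_rows],
        cutoff=cfg.cluster_cutoff, anchor=cfg.cluster_anchor)
    pd.DataFrame([{
        "cluster": c.name, "chromosome": c.chromosome,
        "members": ",".join(c.members), "span_start": c.span[0],
        "span_end": c.span[1], "tandem_duplication": c.tandem_duplication,
    } for c in clusters]).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    report["clusters"] = {"n_clusters": len(clusters),
                          "n_clustered_genes": sum(len(c.members) for c in clusters)}
    _stage("clusters", t0, **report["clusters"])

    # --- conservation ------------------------------------------------------
    uniq: dict[str, hp.MirnaRecord] = {}
    for r in sorted(records, key=lambda r: (-r.total, r.name)):
        uniq.setdefault(r.name, r)
    if cfg.species_dir:
        t0 = time.time()
        species_seqs = {}
        for p in sorted(Path(cfg.species_dir).glob("*.fa")):
            species_seqs[p.stem] = "".join(_read_fasta(p).values())
        calls = cons.conservation_calls(
            {n: r.mature for n, r in uniq.items()}, species_seqs,
            cfg.species_groups)
        pd.DataFrame([{"mirna": c.mirna, "tier": c.tier, **c.status}
                      for c in calls]).to_csv(outdir / "conservation.tsv",
                                              sep="\t", index=False)
        report["tiers"] = cons.tier_counts(calls)
        _stage("conservation", t0, **report["tiers"])

    # --- isomiR -----------------------------------------------------------
    t0 = time.time()
    profiles, assigned, ambiguous = _isomir_profiles(kept, uniq, genome)
    arms = {n: (r.arm or "5p") for n, r in uniq.items()}
    sites = []
    for p in profiles.values():
        sites.extend(iso.call_sites(p, min_total=cfg.min_site_total,
                                    min_rate=cfg.min_site_rate))
    windows, ggu_flags, _ = iso.motif_windows(
        sites, {n: p.canonical for n, p in profiles.items()})
    tails = iso.tailing_summary(profiles.values(), arms)
    _write_isomir_tables(profiles, sites, windows, outdir)
    class_totals: dict[str, int] = {}
    for p in profiles.values():
        for k, v in p.class_counts.items():
            class_totals[k] = class_totals.get(k, 0) + v
    total_assigned = sum(class_totals.values())
    report["isomir"] = {
        "assigned_reads": total_assigned,
        "ambiguous_reads": ambiguous,
        "class_fractions": {k: (v / total_assigned if total_assigned else 0.0)
                            for k, v in sorted(class_totals.items())},
        "n_sites": len(sites),
        "n_ggu_sites": sum(1 for s in sites if s.in_ggu),
        "tailing": {
            "n_u_mirnas": tails["n_u_mirnas"],
            "n_a_mirnas": tails["n_a_mirnas"],
            "arm_crosstab": {f"{b}_{a}": v for (b, a), v in tails["arm_crosstab"].items()},
        },
    }
    _stage("isomir", t0, n_profiles=len(profiles), n_sites=len(sites))

    # --- expression -------------------------------------------------------
    t0 = time.time()
    matrix = pd.DataFrame(
        {s: {n: uniq[n].counts.get(s, 0) for n in sorted(uniq)} for s in samples}
    )
    matrix.to_csv(outdir / "expression_counts.tsv", sep="\t")
    if not matrix.empty and matrix.values.sum() > 0:
        norm = expr.rpm(matrix.loc[:, matrix.sum(axis=0) > 0])
        norm.to_csv(outdir / "expression_rpm.tsv", sep="\t")
        calls = expr.call_tissue_enrichment(
            matrix, min_total=cfg.min_enrich_total, min_share=cfg.min_enrich_share)
        pd.DataFrame([{"mirna": c.mirna, "tissue": c.enriched_tissue or "",
                       "top_share": c.top_share, "total": c.total}
                      for c in calls]).to_csv(outdir / "tissue_enrichment.tsv",
                                              sep="\t", index=False)
        chrom_map = {n: (uniq[n].precursor[0] if uniq[n].precursor else "")
                     for n in uniq}
        ratios = expr.mf_ratio(matrix, chrom_map,
                               pseudocount=cfg.ratio_pseudocount)
        ratios.to_csv(outdir / "mf_ratios.tsv", sep="\t")
        top = matrix.sum(axis=1).sort_values(ascending=False).head(20)
        report["expression"] = {
            "n_enriched": sum(1 for c in calls if c.enriched_tissue),
            "enriched": {c.mirna: c.enriched_tissue for c in calls
                         if c.enriched_tissue},
            "top_expressed": list(top.index),
            "z_linked_ratios": {
                str(i): float(ratios.loc[i, "ratio_overall"])
                for i in ratios.index if ratios.loc[i, "z_linked"]
            } if not ratios.empty else {},
        }
    else:
        report["expression"] = {"n_enriched": 0, "enriched": {},
                                "top_expressed": [], "z_linked_ratios": {}}
    _stage("expression", t0, n_enriched=report["expression"]["n_enriched"])

    # --- targets ----------------------------------------------------------
    if cfg.utrs:
        t0 = time.time()
        utr_records = []
        for name, seq in _read_fasta(cfg.utrs).items():
            gene, _, chrom = name.partition("|")
            utr_records.append(tg.UtrRecord(gene, chrom, seq))
        enrich = {}
        target_rows = []
        for n in sorted(uniq):
            r = uniq[n]
            hit = tg.seed_match(r.mature, utr_records)
            res = tg.fisher_enrichment(hit, utr_records, cfg.enrich_chromosome, n)
            enrich[n] = {
                "n_targets": len(hit),
                "on_chrom": res.table[0][0],
                "p_value": res.p_value,
                "target_fraction": res.target_fraction_on_chrom,
            }
            for g in sorted(hit):
                target_rows.append({"mirna": n, "gene": g})
        pd.DataFrame(target_rows).to_csv(outdir / "targets.tsv", sep="\t", index=False)
        pd.DataFrame(enrich).T.rename_axis("mirna").to_csv(
            outdir / "target_enrichment.tsv", sep="\t")
        report["targets"] = enrich
        _stage("targets", t0, n_mirnas=len(enrich))

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _write_mirna_table(records, samples, path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: (r.name, r.precursor or ("", 0, 0, ""))):
        row = {
            "name": r.name, "mature": r.mature, "arm": r.arm or "",
            "star": r.star or "", "status": r.status,
            "chrom": r.precursor[0] if r.precursor else "",
            "start": r.precursor[1] if r.precursor else "",
            "end": r.precursor[2] if r.precursor else "",
            "strand": r.precursor[3] if r.precursor else "",
            "both_arms_retained": r.both_arms_retained,
            "total": r.total,
        }
        for s in samples:
            row[s] = r.counts.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _isomir_profiles(kept, uniq, genome, context: int = 10):
    """Assign collapsed reads to miRNAs and build isomiR profiles.

    A read is assigned when it classifies against exactly one canonical;
    reads classifiable against several distinct miRNA sequences are
    excluded as ambiguous. Only miRNAs with a genomic precursor window are
    profiled (the template is needed to separate templated from
    untemplated extensions).
    """
    templates = {}
    for n, r in sorted(uniq.items()):
        if not r.precursor:
            continue
        chrom, p_start, p_end, strand = r.precursor
        seq = genome[chrom]
        lo = max(0, p_start - context)
        hi = min(len(seq), p_end + context)
        window = seq[lo:hi]
        mature_dna = r.mature.replace("U", "T")
        if strand == "-":
            window = mp.revcomp(window)
        off = window.find(mature_dna)
        if off < 0:
            continue
        templates[n] = (window.replace("T", "U"), off)

    assignments: dict[str, list[tuple[str, int]]] = {n: [] for n in templates}
    ambiguous = 0
    for read in kept:
        seq = read.sequence.upper().replace("U", "T")
        hits = []
        for n, (template, off) in templates.items():
            t_dna = template.replace("U", "T")
            if seq[:8] not in t_dna and seq[-8:] not in t_dna:
                continue
            cls, _ = iso.classify_read(seq, uniq[n].mature, template, off)
            if cls != "unclassified":
                hits.append(n)
        mature_seqs = {uniq[n].mature for n in hits}
        if len(mature_seqs) > 1:
            ambiguous += read.total
            continue
        if hits:
            assignments[hits[0]].append((seq, read.total))

    profiles = {}
    for n, reads in assignments.items():
        if not reads:
            continue
        template, off = templates[n]
        profiles[n] = iso.build_profile(n, uniq[n].mature, template, off, reads)
    return profiles, assignments, ambiguous


def _write_isomir_tables(profiles, sites, windows, outdir: Path) -> None:
    rows = []
    for n in sorted(profiles):
        p = profiles[n]
        row = {"mirna": n, "canonical": p.canonical, "total": p.total,
               "unclassified": p.unclassified}
        row.update({k: p.class_counts.get(k, 0) for k in iso.VARIANT_CLASSES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "isomir_profiles.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "mirna": s.mirna, "position": s.position, "reference": s.reference,
        "alternates": ",".join(f"{b}:{n}" for b, n in sorted(s.alternates.items())),
        "rate": s.rate, "in_ggu": s.in_ggu, "in_seed": s.in_seed,
        "putative_editing": s.putative_editing, "error_pvalue": s.error_pvalue,
    } for s in sites]).to_csv(outdir / "substitution_sites.tsv", sep="\t", index=False)
    if windows:
        ic, freqs = iso.information_content(windows)
        pd.DataFrame(freqs, columns=list("ACGU")).assign(ic=ic).rename_axis(
            "position").to_csv(outdir / "motif_logo.tsv", sep="\t")


def table_fixtures(table: int) -> pd.DataFrame:
    """Built-in printed datasets (1: brain-enriched counts; 2: GGU motif)."""
    if table == 1:
        return fixtures.table1()
    if table == 2:
        return fixtures.table2()
    raise ValueError("table must be 1 or 2")
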
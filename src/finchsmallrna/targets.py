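"""Seed-match target prediction and per-chromosome enrichment statistics.

A gene is a putative target of a miRNA when its 3'UTR contains a perfect
match to the reverse complement of the miRNA seed (mature positions 2-8, a
7-mer). Enrichment of targets on a chromosome (the Z-chromosome dosage
question) is tested with a one-sided Fisher exact test, i.e. the upper
hypergeometric tail of the 2x2 table over the UTR-bearing gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

MIN_UTR_LEN = 10
SEED_START = 2   # 1-based, inclusive
SEED_END = 8

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class UtrRecord:
    gene: str
    chromosome: str
    utr: str


@dataclass
class EnrichmentResult:
    mirna: str
    chromosome: str
    table: tuple[tuple[int, int], tuple[int, int]]
    # ((targets on chrom, targets elsewhere),
    #  (non-target genes on chrom, non-target genes elsewhere))
    p_value: float
    target_fraction_on_chrom: float


def seed_site(mature: str) -> str:
    """DNA reverse complement of the seed (positions 2-8) of ``mature``."""
    seq = mature.upper().replace("U", "T")
    if len(seq) < SEED_END:
        raise ValueError(f"mature sequence shorter than {SEED_END} nt")
    seed = seq[SEED_START - 1:SEED_END]
    return seed.translate(_COMP)[::-1]


def filter_utrs(utrs: Iterable[UtrRecord], min_len: int = MIN_UTR_LEN) -> list[UtrRecord]:
    """Drop genes whose 3'UTR is shorter than ``min_len`` nt."""
    return [u for u in utrs if len(u.utr) >= min_len]


def seed_match(mature: str, utrs: Sequence[UtrRecord]) -> set[str]:
    """Genes whose 3'UTR contains the seed-match site (sense strand only).

    Matching is case- and U/T-insensitive; each gene counts once however
    many sites it carries. UTRs shorter than the minimum are excluded.
    """
    site = seed_site(mature)
    targets = set()
    for u in filter_utrs(utrs):
        if site in u.utr.upper().replace("U", "T"):
            targets.add(u.gene)
    return targets


def fisher_enrichment(targets: set[str], utrs: Sequence[UtrRecord],
                      chromosome: str, mirna: str = "") -> EnrichmentResult:
    """One-sided (greater) enrichment of targets on ``chromosome``.

    The universe is every UTR-bearing gene after the length filter. The
    p-value is the exact upper hypergeometric tail; no chi-square
    approximation.
    """
    universe = filter_utrs(utrs)
    if not universe:
        raise ValueError("empty gene universe")
    n_genes = len(universe)
    on_chrom = {u.gene for u in universe if u.chromosome == chromosome}
    n_targets = len(targets)
    t_on = len(targets & on_chrom)
    t_off = n_targets - t_on
    nt_on = len(on_chrom) - t_on
    nt_off = (n_genes - len(on_chrom)) - t_off
    # P(X >= t_on), X ~ Hypergeom(N=n_genes, K=|on_chrom|, n=n_targets)
    p = float(stats.hypergeom.sf(t_on - 1, n_genes, len(on_chrom), n_targets))
    p = min(1.0, max(p, 0.0))
    frac = t_on / n_targets if n_targets else 0.0
    return EnrichmentResult(
        mirna=mirna, chromosome=chromosome,
        table=((t_on, t_off), (nt_on, nt_off)),
        p_value=p, target_fraction_on_chrom=frac,
    )


def chromosome_percent(n_on: int, n_total: int, decimals: int = 1) -> float:
    """Share of targets on one chromosome as a printed percentage."""
    if n_total <= 0:
        raise ValueError("no targets")
    return round(100.0 * n_on / n_total, decimals)


def target_report(targets: set[str], utrs: Sequence[UtrRecord]) -> pd.DataFrame:
    """Per-chromosome target counts and percentages next to the gene
    background distribution."""
    universe = filter_utrs(utrs)
    chrom_of = {u.gene: u.chromosome for u in universe}
    per_chrom: dict[str, int] = {}
    bg: dict[str, int] = {}
    for u in universe:
        bg[u.chromosome] = bg.get(u.chromosome, 0) + 1
    for g in targets:
        c = chrom_of.get(g)
        if c is not None:
            per_chrom[c] = per_chrom.get(c, 0) + 1
    n_t = sum(per_chrom.values())
    n_g = sum(bg.values())
    rows = []
    for chrom in sorted(bg):
        t = per_chrom.get(chrom, 0)
        if n_t == 0:
            continue
        rows.append({
            "chromosome": chrom,
            "targets": t,
            "target_percent": chromosome_percent(t, n_t),
            "genes": bg[chrom],
            "gene_percent": chromosome_percent(bg[chrom], n_g),
        })
    return pd.DataFrame(rows)
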
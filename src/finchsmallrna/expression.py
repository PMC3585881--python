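"""Count normalization, tissue-enrichment and male:female expression ratios.

Counts are normalized per library to Reads Per Million miRNA reads (RPM).
A miRNA is called enriched in one tissue when it has at least ``min_total``
reads over all tissues combined (sexes pooled) and a single tissue carries
at least 90% of those reads. Male:female ratios are computed on RPM with a
pseudocount; Z-linked miRNAs in a genome without chromosome-wide dosage
compensation are expected near the 2:1 copy-number ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

MIN_ENRICH_TOTAL = 100
MIN_ENRICH_SHARE = 0.90
RATIO_PSEUDOCOUNT = 0.5
MIN_RATIO_TOTAL = 100


def rpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization per sample (column).

    Column sums of the result equal 1e6 (over the miRNAs in the matrix).
    """
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total miRNA reads in sample(s): {bad}")
    return matrix * 1e6 / totals


@dataclass
class EnrichmentCall:
    mirna: str
    enriched_tissue: Optional[str]
    top_share: float
    total: int


def combine_sexes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum (tissue, sex) columns into per-tissue columns.

    Columns may be a 2-level MultiIndex (tissue, sex) or strings like
    ``brain_M``; plain per-tissue columns pass through unchanged.
    """
    if isinstance(matrix.columns, pd.MultiIndex):
        return matrix.T.groupby(level=0).sum().T
    split = [c.rsplit("_", 1) for c in matrix.columns]
    if all(len(p) == 2 and p[1] in ("M", "F") for p in split):
        tissues = [p[0] for p in split]
        out = matrix.T.groupby(tissues).sum().T
        return out
    return matrix


def call_tissue_enrichment(matrix: pd.DataFrame, *,
                           min_total: int = MIN_ENRICH_TOTAL,
                           min_share: float = MIN_ENRICH_SHARE) -> list[EnrichmentCall]:
    """Call single-tissue-enriched miRNAs from a per-tissue count matrix.

    Sexes are pooled first when the columns carry sex labels. The call is
    invariant to uniform scaling of all samples; ties for the top tissue
    break to not-enriched.
    """
    per_tissue = combine_sexes(matrix)
    calls = []
    for mirna, row in per_tissue.iterrows():
        total = float(row.sum())
        if total <= 0:
            calls.append(EnrichmentCall(str(mirna), None, 0.0, 0))
            continue
        top = row.max()
        share = float(top / total)
        tied = (row == top).sum() > 1
        ok = (total >= min_total) and (share >= min_share) and not tied
        calls.append(EnrichmentCall(
            str(mirna), str(row.idxmax()) if ok else None, share, int(round(total))))
    return calls


def enrichment_percent(n_enriched: int, n_total: int, decimals: int = 0) -> float:
    """Share of the repertoire enriched in a single tissue, as printed."""
    if n_total <= 0:
        raise ValueError("empty repertoire")
    pct = 100.0 * n_enriched / n_total
    return round(pct, decimals) if decimals else float(round(pct))


def mf_ratio(matrix: pd.DataFrame, chrom_map: Mapping[str, str], *,
             pseudocount: float = RATIO_PSEUDOCOUNT,
             min_total: int = MIN_RATIO_TOTAL) -> pd.DataFrame:
    """Per-miRNA, per-tissue male:female expression ratios on RPM.

    ``matrix`` columns are ``tissue_SEX`` strings or a (tissue, sex)
    MultiIndex. miRNAs with fewer than ``min_total`` raw reads combined are
    excluded. The result carries the ratio and its log2 per tissue, an
    overall ratio over pooled tissues, and a Z-linkage flag from
    ``chrom_map``.
    """
    if isinstance(matrix.columns, pd.MultiIndex):
        cols = [(t, s) for t, s in matrix.columns]
    else:
        cols = [tuple(c.rsplit("_", 1)) for c in matrix.columns]
    tissues = sorted({t for t, _ in cols})
    norm = rpm(matrix)
    rows = []
    for mirna in matrix.index:
        total = float(matrix.loc[mirna].sum())
        if total < min_total:
            continue
        rec: dict = {"mirna": mirna,
                     "chromosome": chrom_map.get(mirna, ""),
                     "z_linked": "Z" in str(chrom_map.get(mirna, "")).upper(),
                     "total_reads": int(round(total))}
        m_all = f_all = 0.0
        for t in tissues:
            m = sum(float(norm.loc[mirna, c if isinstance(matrix.columns, pd.MultiIndex) else f"{c[0]}_{c[1]}"])
                    for c in cols if c[0] == t and c[1] == "M")
            f = sum(float(norm.loc[mirna, c if isinstance(matrix.columns, pd.MultiIndex) else f"{c[0]}_{c[1]}"])
                    for c in cols if c[0] == t and c[1] == "F")
            ratio = (m + pseudocount) / (f + pseudocount)
            rec[f"ratio_{t}"] = ratio
            rec[f"log2_ratio_{t}"] = float(np.log2(ratio))
            m_all += m
            f_all += f
        rec["ratio_overall"] = (m_all + pseudocount) / (f_all + pseudocount)
        rec["log2_ratio_overall"] = float(np.log2(rec["ratio_overall"]))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("mirna") if rows else pd.DataFrame()
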
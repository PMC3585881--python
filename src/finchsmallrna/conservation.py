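"""Cross-species conservation tiers and genomic clustering of miRNA genes.

A mature sequence counts as conserved in another species only when a
<= 1-mismatch occurrence of it sits inside a foldable hairpin context in
that species' sequence set; a mature-sequence hit without a hairpin is
recorded as ``mature-only`` and does not count as a homolog. Tiers are a
deterministic function of which species groups carry homologs. miRNA genes
within 10 kb of each other on the same chromosome form genomic clusters
named after the first member, e.g. ``mir-24(3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .hairpin import detect_hairpin, fold_max_pairs
from .mapping import revcomp

CLUSTER_CUTOFF = 10_000
WINDOW_LENGTHS = (120, 100, 80, 60)
WINDOW_PAD = 10

TIERS = ("species-specific", "avian-specific", "avian+mammal",
         "vertebrate", "pan-animal")


@dataclass
class ConservationCall:
    mirna: str
    status: dict[str, str] = field(default_factory=dict)  # species -> status
    tier: Optional[str] = None


def _hits(seq: str, hay: str, max_mismatch: int) -> list[int]:
    n = len(seq)
    out = []
    for start in range(0, len(hay) - n + 1):
        mm = 0
        window = hay[start:start + n]
        for a, b in zip(window, seq):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append(start)
    return out


def find_homolog(mature: str, species_seq: str, *, max_mismatch: int = 1,
                 window_lengths: Sequence[int] = WINDOW_LENGTHS,
                 pad: int = WINDOW_PAD) -> str:
    """Homology status of one mature miRNA in one species' sequence set.

    Returns ``precursor-homolog`` when a <= ``max_mismatch`` occurrence sits
    inside a window folding into a miRNA-like hairpin, ``mature-only`` when
    occurrences exist but none fold, and ``absent`` otherwise.
    """
    dna = mature.upper().replace("U", "T")
    hay = species_seq.upper().replace("U", "T")
    found = False
    for strand_seq in (dna, revcomp(dna)):
        for pos in _hits(strand_seq, hay, max_mismatch):
            found = True
            n = len(dna)
            for W in window_lengths:
                for w_start in (pos - pad, pos + n + pad - W):
                    w_start = max(0, min(w_start, len(hay) - W))
                    w_end = w_start + W
                    if not (w_start <= pos and pos + n <= w_end):
                        continue
                    window = hay[w_start:w_end].replace("T", "U")
                    local = (pos - w_start + 1, pos - w_start + n)
                    if detect_hairpin(fold_max_pairs(window), local).is_hairpin:
                        return "precursor-homolog"
    return "mature-only" if found else "absent"


def assign_tier(status: Mapping[str, str],
                species_groups: Mapping[str, str]) -> str:
    """Conservation tier from per-species homology statuses.

    ``species_groups`` maps species name to one of ``avian``, ``mammal``,
    ``vertebrate_other``, ``invertebrate``. Only ``precursor-homolog`` (or a
    miRBase-known annotation, status ``known-in-miRBase``) counts.
    """
    if not species_groups:
        raise ValueError("empty species set")
    groups = {g: False for g in ("avian", "mammal", "vertebrate_other", "invertebrate")}
    for sp, st in status.items():
        if st in ("precursor-homolog", "known-in-miRBase"):
            g = species_groups.get(sp)
            if g is None:
                raise ValueError(f"species {sp!r} not assigned to a group")
            groups[g] = True
    if groups["invertebrate"]:
        return "pan-animal"
    if groups["vertebrate_other"]:
        return "vertebrate"
    if groups["mammal"]:
        return "avian+mammal"
    if groups["avian"]:
        return "avian-specific"
    return "species-specific"


def conservation_calls(
    matures: Mapping[str, str],
    species_seqs: Mapping[str, str],
    species_groups: Mapping[str, str],
    **kwargs,
) -> list[ConservationCall]:
    calls = []
    for name in sorted(matures):
        st = {sp: find_homolog(matures[name], species_seqs[sp], **kwargs)
              for sp in sorted(species_seqs)}
        calls.append(ConservationCall(name, st, assign_tier(st, species_groups)))
    return calls


def tier_counts(calls: Iterable[ConservationCall]) -> dict[str, int]:
    out = {t: 0 for t in TIERS}
    for c in calls:
        out[c.tier] += 1
    return out


def tier_percentages(counts: Mapping[str, int], decimals: int = 0) -> dict[str, float]:
    """Tier shares as percentages of the repertoire, at printed precision."""
    total = sum(counts.values())
    if total == 0:
        return {}
    return {t: round(100.0 * n / total, decimals) if decimals else
            round(100.0 * n / total) for t, n in counts.items()}


# ---------------------------------------------------------------------------
# genomic clusters

@dataclass
class ClusterRecord:
    name: str                     # "<first-member>(<n>)"
    members: list[str]
    chromosome: str
    span: tuple[int, int]
    tandem_duplication: bool = False


def cluster_loci(
    loci: Sequence[tuple],
    cutoff: int = CLUSTER_CUTOFF,
    *,
    anchor: str = "start",
) -> list[ClusterRecord]:
    """Single-linkage clustering of miRNA genes along each chromosome.

    ``loci``: (name, chromosome, start, mature-sequence-or-None) or with an
    extra ``end`` element, (name, chromosome, start, end, mature). Adjacent
    loci on the same chromosome whose start-to-start gap (``anchor='start'``,
    the default) or end-to-start gap (``anchor='end'``) is <= ``cutoff``
    chain into one cluster; singletons are not clusters. Strand is ignored.
    A cluster whose members share an identical mature sequence is flagged
    as a tandem duplication.
    """
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    by_chrom: dict[str, list] = {}
    for row in loci:
        if len(row) == 5:
            name, chrom, start, end, seq = row
        else:
            name, chrom, start, seq = row
            end = start
        by_chrom.setdefault(chrom, []).append((start, end, name, seq))
    clusters = []

    def _flush(chrom: str, group: list) -> None:
        if len(group) < 2:
            return
        names = [n for _, _, n, _ in group]
        seqs = [s for _, _, _, s in group if s]
        dup = len(seqs) >= 2 and len(set(seqs)) < len(seqs)
        clusters.append(ClusterRecord(
            name=f"{names[0]}({len(names)})",
            members=names, chromosome=chrom,
            span=(group[0][0], max(e for _, e, _, _ in group)),
            tandem_duplication=dup,
        ))

    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom])
        group: list = []
        for row in rows:
            if group:
                prev_anchor = group[-1][0] if anchor == "start" else group[-1][1]
                if row[0] - prev_anchor > cutoff:
                    _flush(chrom, group)
                    group = []
            group.append(row)
        _flush(chrom, group)
    return clusters
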
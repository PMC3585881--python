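"""Exact-match genome mapping and small-RNA class partition.

Collapsed inserts are matched to the genome with no mismatches on both
strands; all occurrences are reported. Reads hitting more than 100 loci are
excluded from annotation; reads with no genomic hit are retained as
``unmapped`` for later homology rescue against known miRNAs. Mapped reads
are then partitioned into classes with a fixed precedence: homology to
known structural ncRNAs (tRNA/rRNA/ncRNA, at most one mismatch) beats
repeat-interval overlap, which beats miRNA candidacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .preprocess import CollapsedRead

MAX_LOCI = 100

RNA_CLASSES = (
    "miRNA-candidate", "tRNA/rRNA/ncRNA", "repeat",
    "mRNA-degradation", "unmapped", "excluded", "undefined",
)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MappedRead:
    sequence: str
    counts: dict[str, int]
    loci: list[tuple[str, int, str]] = field(default_factory=list)  # chrom, 0-based start, strand
    rna_class: str = "undefined"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_exact(reads: Iterable[CollapsedRead], genome: Mapping[str, str],
              max_loci: int = MAX_LOCI) -> list[MappedRead]:
    """Map collapsed reads to the genome, exact match, both strands.

    Minus-strand hits are reported on forward coordinates: the locus start
    is the forward position of the reverse-complement occurrence.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    genome_up = {c: genome[c].upper() for c in genome}
    out = []
    for r in reads:
        seq = r.sequence.upper().replace("U", "T")
        rc = revcomp(seq)
        loci: list[tuple[str, int, str]] = []
        for chrom in sorted(genome_up):
            hay = genome_up[chrom]
            for pos in _find_all(hay, seq):
                loci.append((chrom, pos, "+"))
            for pos in _find_all(hay, rc):
                loci.append((chrom, pos, "-"))
        m = MappedRead(sequence=seq, counts=dict(r.counts))
        if len(loci) > max_loci:
            m.rna_class = "excluded"
        elif not loci:
            m.rna_class = "unmapped"
        else:
            m.loci = loci
            m.rna_class = "miRNA-candidate"  # provisional; refined by classify_reads
        out.append(m)
    return out


def _homologous(seq: str, refs: Mapping[str, str], max_mismatch: int = 1) -> bool:
    """Hamming-distance scan of equal-length windows over each reference."""
    n = len(seq)
    targets = (seq, revcomp(seq))
    for name in refs:
        ref = refs[name].upper().replace("U", "T")
        for start in range(0, len(ref) - n + 1):
            window = ref[start:start + n]
            for t in targets:
                mm = 0
                for a, b in zip(window, t):
                    if a != b:
                        mm += 1
                        if mm > max_mismatch:
                            break
                else:
                    return True
    return False


def _read_bed(path) -> list[tuple[str, int, int]]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}: {line!r}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as e:
                raise ValueError(f"malformed BED line {ln}: {line!r}") from e
    return rows


def classify_reads(
    mapped: Iterable[MappedRead],
    *,
    repeat_intervals: Optional[Sequence[tuple[str, int, int]]] = None,
    known_ncrna: Optional[Mapping[str, str]] = None,
    transcripts: Optional[Mapping[str, str]] = None,
    max_mismatch: int = 1,
) -> list[MappedRead]:
    """Assign each mapped read to exactly one small-RNA class.

    Precedence: ncRNA homology > repeat overlap > mRNA degradation (only
    when a transcript set is supplied) > miRNA candidate; unmapped and
    excluded reads keep their class. ``repeat_intervals`` may be a parsed
    list or a BED file path.
    """
    if isinstance(repeat_intervals, (str, bytes)) or hasattr(repeat_intervals, "__fspath__"):
        repeat_intervals = _read_bed(repeat_intervals)
    reps = repeat_intervals or []
    out = []
    for m in mapped:
        if m.rna_class in ("unmapped", "excluded"):
            out.append(m)
            continue
        if known_ncrna and _homologous(m.sequence, known_ncrna, max_mismatch):
            m.rna_class = "tRNA/rRNA/ncRNA"
        elif any(_overlaps(m, reps)):
            m.rna_class = "repeat"
        elif transcripts and _homologous(m.sequence, transcripts, 0):
            m.rna_class = "mRNA-degradation"
        else:
            m.rna_class = "miRNA-candidate"
        out.append(m)
    return out


def _overlaps(m: MappedRead, intervals) -> Iterable[bool]:
    n = len(m.sequence)
    for chrom, start, strand in m.loci:
        end = start + n
        for c, a, b in intervals:
            if c == chrom and start < b and end > a:
                yield True


def class_summary(mapped: Iterable[MappedRead]) -> dict[str, float]:
    """Read-weighted class fractions over all reads (the library overview)."""
    totals: dict[str, int] = {}
    for m in mapped:
        totals[m.rna_class] = totals.get(m.rna_class, 0) + m.total
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {k: v / grand for k, v in sorted(totals.items())}
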
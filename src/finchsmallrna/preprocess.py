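"""Demultiplexing, adapter trimming, collapsing and read filtering.

Library layout: each 36-nt read is ``insert + pentamer barcode + 3' adapter
constant region`` (the adapter is truncated by the read end). Trimming
locates the longest prefix of the constant adapter at the read end (at
least 6 nt), takes the 5 nt immediately upstream as the barcode and the
remainder as the insert. Inserts of 18-32 nt are kept, collapsed to unique
sequences with per-sample counts; singletons across all samples (orphans)
are then removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO

ADAPTER3 = "TCGTATGCCGTCTTCTGCTTGT"
MIN_ADAPTER_MATCH = 6
MIN_INSERT = 18
MAX_INSERT = 32
BARCODE_LEN = 5


@dataclass
class CollapsedRead:
    """A unique insert sequence with per-sample read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class QCTally:
    n_records: int = 0
    n_kept: int = 0
    no_adapter: int = 0
    unknown_barcode: int = 0
    bad_length: int = 0
    low_quality: int = 0

    def dropped(self) -> int:
        return self.no_adapter + self.unknown_barcode + self.bad_length + self.low_quality


def _find_adapter(read: str, adapter: str = ADAPTER3,
                  min_match: int = MIN_ADAPTER_MATCH) -> int | None:
    """Length of the longest adapter prefix terminating the read, or None."""
    max_l = min(len(adapter), len(read) - BARCODE_LEN)
    for L in range(max_l, min_match - 1, -1):
        if read.endswith(adapter[:L]):
            return L
    return None


def trim_record(read: str, barcode_map: Mapping[str, str],
                tally: QCTally) -> tuple[str, str] | None:
    """Split one raw read into (insert, sample); tally and drop failures."""
    read = read.upper()
    if "N" in read:
        tally.low_quality += 1
        return None
    L = _find_adapter(read)
    if L is None:
        tally.no_adapter += 1
        return None
    barcode = read[-L - BARCODE_LEN:-L]
    insert = read[:-L - BARCODE_LEN]
    sample = barcode_map.get(barcode)
    if sample is None:
        tally.unknown_barcode += 1
        return None
    if not (MIN_INSERT <= len(insert) <= MAX_INSERT):
        tally.bad_length += 1
        return None
    return insert, sample


def trim_and_demux(fastq, barcode_map: Mapping[str, str]):
    """Demultiplex and collapse a FASTQ stream.

    ``fastq`` may be a path/handle (parsed with Biopython) or an iterable of
    raw sequence strings. Returns ``(collapsed, tally)`` where ``collapsed``
    is a list of :class:`CollapsedRead` sorted by sequence.
    """
    if not barcode_map:
        raise ValueError("empty barcode map")
    if any(len(bc) != BARCODE_LEN for bc in barcode_map):
        raise ValueError("barcodes must be pentamers")
    if len(set(barcode_map)) != len(barcode_map):
        raise ValueError("duplicate barcodes")

    if isinstance(fastq, (str, bytes)) or hasattr(fastq, "read"):
        seqs: Iterable[str] = (str(rec.seq) for rec in SeqIO.parse(fastq, "fastq"))
    else:
        seqs = fastq

    tally = QCTally()
    counts: dict[str, dict[str, int]] = {}
    for i, seq in enumerate(seqs):
        tally.n_records += 1
        if not seq:
            raise ValueError(f"unreadable FASTQ record at index {i}")
        hit = trim_record(seq, barcode_map, tally)
        if hit is None:
            continue
        insert, sample = hit
        tally.n_kept += 1
        per = counts.setdefault(insert, {})
        per[sample] = per.get(sample, 0) + 1

    collapsed = [CollapsedRead(seq, counts[seq]) for seq in sorted(counts)]
    return collapsed, tally


def drop_orphans(collapsed: Iterable[CollapsedRead]) -> list[CollapsedRead]:
    """Remove orphan sequences: inserts seen exactly once across all samples."""
    return [r for r in collapsed if r.total > 1]


def write_counts_tsv(collapsed: Iterable[CollapsedRead], samples: list[str],
                     fh: TextIO) -> None:
    fh.write("sequence\t" + "\t".join(samples) + "\n")
    for r in collapsed:
        fh.write(r.sequence + "\t" +
                 "\t".join(str(r.counts.get(s, 0)) for s in samples) + "\n")
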
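"""isomiR classification, substitution-site calling and motif analysis.

Every read assigned to a single miRNA is placed in exactly one variant
class: canonical, 5'/3'/both-end genome-templated length variant,
untemplated 3' addition (A, U or other), or internal substitution.
Alignment to the canonical sequence is end-anchored sliding with no indels
(length variation is treated as strictly terminal): the read is compared
against the genomic template at 5' offsets of up to +/-4 nt, and trailing
3' bases that disagree with the template are untemplated tail candidates.

Site calling follows hard filters typical of sequencing-based editing
scans: a site is reported when the miRNA has more than ``min_total`` reads
in total, mismatched reads exceed ``min_rate`` of them, and the position
is at least ``min_end_distance`` nt away from either terminus. A->G sites
are additionally flagged as putative A-to-I editing. The 6-nt motif
analysis extracts windows with the substituted base at position 3 so a
reference GGU triplet ending at the site occupies window positions 1-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

VARIANT_CLASSES = (
    "canonical", "5p-length-variant", "3p-length-variant", "both-ends",
    "untemplated-A", "untemplated-U", "untemplated-other",
    "internal-substitution",
)

MAX_END_OFFSET = 4
MAX_INTERNAL_MISMATCH = 2
MAX_TAIL = 2

MIN_TOTAL_READS = 100
MIN_SITE_RATE = 0.05
MIN_END_DISTANCE = 2
SEQ_ERROR_RATE = 0.005

_RNA = "ACGU"


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class IsomirProfile:
    """Per-miRNA variant-class counts and positionwise substitutions."""

    mirna: str
    canonical: str                             # RNA
    class_counts: dict[str, int] = field(default_factory=dict)
    subst: Optional[np.ndarray] = None         # 4 x L counts, rows ACGU
    total: int = 0
    unclassified: int = 0
    tail_counts: dict[str, int] = field(default_factory=dict)  # tail seq -> reads

    def __post_init__(self):
        self.canonical = _to_rna(self.canonical)
        if self.subst is None:
            self.subst = np.zeros((4, len(self.canonical)), dtype=int)
        for c in VARIANT_CLASSES:
            self.class_counts.setdefault(c, 0)


@dataclass
class SubstitutionSite:
    mirna: str
    position: int           # 1-based on the canonical
    reference: str
    alternates: dict[str, int]
    rate: float
    in_ggu: bool
    in_seed: bool
    putative_editing: bool
    error_pvalue: float     # binomial tail against the sequencing error floor


def classify_read(read: str, canonical: str, template: str,
                  canonical_offset: int) -> tuple[str, dict]:
    """Classify one read against a canonical miRNA and its genomic template.

    ``template`` is the genomic sequence (RNA alphabet, mature strand
    orientation) of a window containing the canonical; ``canonical_offset``
    is the 0-based start of the canonical within it. Returns
    ``(variant class, details)``; class ``unclassified`` when the read
    cannot be aligned within +/-4 nt terminal offsets, <= 2 internal
    mismatches and a tail of <= 2 nt.
    """
    read = _to_rna(read)
    canonical = _to_rna(canonical)
    template = _to_rna(template)
    L = len(canonical)

    best = None
    for d5 in range(-MAX_END_OFFSET, MAX_END_OFFSET + 1):
        t_start = canonical_offset + d5
        if t_start < 0 or t_start + len(read) > len(template):
            continue
        ref = template[t_start:t_start + len(read)]
        mism = [i for i, (a, b) in enumerate(zip(read, ref)) if a != b]
        # trailing run of mismatches at the 3' end = candidate untemplated tail
        tail_len = 0
        while tail_len < len(mism) and mism[len(mism) - 1 - tail_len] == len(read) - 1 - tail_len:
            tail_len += 1
        tail_len = min(tail_len, MAX_TAIL)
        internal = [i for i in mism if i < len(read) - tail_len]
        d3 = (t_start + len(read) - tail_len) - (canonical_offset + L)
        key = (len(internal), abs(d5) + abs(d3), tail_len)
        if best is None or key < best[0]:
            best = (key, d5, d3, tail_len, internal)
    if best is None:
        return "unclassified", {}
    (_, d5, d3, tail_len, internal) = best
    if len(internal) > MAX_INTERNAL_MISMATCH or abs(d3) > MAX_END_OFFSET:
        return "unclassified", {}

    details = {"d5": d5, "d3": d3, "tail": read[len(read) - tail_len:] if tail_len else "",
               "internal": []}
    for i in internal:
        pos = i + d5 + 1  # 1-based position on the canonical
        if 1 <= pos <= L:
            details["internal"].append((pos, canonical[pos - 1], read[i]))

    if tail_len:
        tail = details["tail"]
        if set(tail) == {"A"}:
            return "untemplated-A", details
        if set(tail) == {"U"}:
            return "untemplated-U", details
        return "untemplated-other", details
    if details["internal"]:
        return "internal-substitution", details
    if d5 != 0 and d3 != 0:
        return "both-ends", details
    if d5 != 0:
        return "5p-length-variant", details
    if d3 != 0:
        return "3p-length-variant", details
    return "canonical", details


def build_profile(mirna: str, canonical: str, template: str, canonical_offset: int,
                  reads: Iterable[tuple[str, int]]) -> IsomirProfile:
    """Accumulate an :class:`IsomirProfile` from (read sequence, count) pairs."""
    prof = IsomirProfile(mirna=mirna, canonical=canonical)
    for seq, n in reads:
        cls, det = classify_read(seq, canonical, template, canonical_offset)
        if cls == "unclassified":
            prof.unclassified += n
            continue
        prof.class_counts[cls] += n
        prof.total += n
        for pos, _ref, alt in det.get("internal", []):
            prof.subst[_RNA.index(alt), pos - 1] += n
        if det.get("tail"):
            prof.tail_counts[det["tail"]] = prof.tail_counts.get(det["tail"], 0) + n
    return prof


def call_sites(prof: IsomirProfile, *, min_total: int = MIN_TOTAL_READS,
               min_rate: float = MIN_SITE_RATE,
               min_end_distance: int = MIN_END_DISTANCE,
               error_rate: float = SEQ_ERROR_RATE) -> list[SubstitutionSite]:
    """Internal-substitution sites passing the depth/rate/position filters.

    The rate is summed across alternate bases at a position. Positions
    within ``min_end_distance`` nt of either terminus are never called.
    """
    sites = []
    if prof.total <= min_total:
        return sites
    L = len(prof.canonical)
    for pos in range(1 + min_end_distance, L + 1 - min_end_distance):
        col = prof.subst[:, pos - 1]
        n_mm = int(col.sum())
        rate = n_mm / prof.total
        if rate <= min_rate:
            continue
        ref = prof.canonical[pos - 1]
        alts = {_RNA[b]: int(col[b]) for b in range(4) if col[b] > 0}
        in_ggu = pos >= 3 and prof.canonical[pos - 3:pos] == "GGU"
        pval = float(stats.binom.sf(n_mm - 1, prof.total, error_rate))
        sites.append(SubstitutionSite(
            mirna=prof.mirna, position=pos, reference=ref, alternates=alts,
            rate=rate, in_ggu=in_ggu, in_seed=2 <= pos <= 8,
            putative_editing=(ref == "A" and "G" in alts),
            error_pvalue=pval,
        ))
    return sites


# ---------------------------------------------------------------------------
# motif windows and information content

def find_ggu_sites(canonical: str) -> list[int]:
    """1-based positions of the U of each GGU triplet in a mature sequence."""
    seq = _to_rna(canonical)
    return [i + 3 for i in range(len(seq) - 2) if seq[i:i + 3] == "GGU"]


def motif_windows(sites: Iterable[SubstitutionSite],
                  canonicals: Mapping[str, str], k: int = 6,
                  offset: int = 3) -> tuple[list[str], dict[tuple[str, int], bool], int]:
    """Extract k-nt windows around substitution sites.

    The substituted base sits at window position ``offset`` (1-based), so
    with the defaults a reference GGU triplet ending at the site occupies
    window positions 1-3. Sites lacking ``offset - 1`` nt of 5' context or
    ``k - offset`` nt of 3' context are dropped and tallied. Returns
    ``(windows, in_ggu flags keyed by (mirna, position), n_dropped)``.
    """
    windows: list[str] = []
    flags: dict[tuple[str, int], bool] = {}
    dropped = 0
    for s in sites:
        seq = _to_rna(canonicals[s.mirna])
        lo = s.position - offset          # 0-based window start
        hi = lo + k
        if lo < 0 or hi > len(seq):
            dropped += 1
            continue
        windows.append(seq[lo:hi])
        flags[(s.mirna, s.position)] = s.position >= 3 and seq[s.position - 3:s.position] == "GGU"
    return windows, flags, dropped


def information_content(windows: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-position information content (bits) and base frequencies.

    IC = 2 - H where H is the Shannon entropy (log2) of the A/C/G/U
    frequencies in a column; no small-sample correction is applied.
    """
    if not windows:
        raise ValueError("empty window set")
    k = len(windows[0])
    if any(len(w) != k for w in windows):
        raise ValueError("windows must share one length")
    freqs = np.zeros((k, 4))
    for w in windows:
        for i, b in enumerate(_to_rna(w)):
            freqs[i, _RNA.index(b)] += 1
    freqs /= len(windows)
    ic = np.empty(k)
    for i in range(k):
        h = -sum(p * math.log2(p) for p in freqs[i] if p > 0)
        ic[i] = 2.0 - h
    return ic, freqs


# ---------------------------------------------------------------------------
# tailing summary

def tailing_summary(profiles: Iterable[IsomirProfile],
                    arms: Mapping[str, str]) -> dict:
    """Untemplated-addition overview across miRNAs.

    Counts miRNAs with any U or A additions, cross-tabulates them by arm
    (5p/3p), and reports the extended/non-extended read ratio per miRNA.
    """
    u_mirnas, a_mirnas = [], []
    crosstab = {("A", "5p"): 0, ("A", "3p"): 0, ("U", "5p"): 0, ("U", "3p"): 0}
    ratios = {}
    for p in profiles:
        u = p.class_counts.get("untemplated-U", 0)
        a = p.class_counts.get("untemplated-A", 0)
        other = p.class_counts.get("untemplated-other", 0)
        arm = arms.get(p.mirna)
        if u > 0:
            u_mirnas.append(p.mirna)
            if arm in ("5p", "3p"):
                crosstab[("U", arm)] += 1
        if a > 0:
            a_mirnas.append(p.mirna)
            if arm in ("5p", "3p"):
                crosstab[("A", arm)] += 1
        canon = p.class_counts.get("canonical", 0)
        extended = u + a + other
        if canon > 0:
            ratios[p.mirna] = extended / canon
    return {
        "n_u_mirnas": len(u_mirnas), "n_a_mirnas": len(a_mirnas),
        "u_mirnas": u_mirnas, "a_mirnas": a_mirnas,
        "arm_crosstab": crosstab, "extended_ratio": ratios,
    }
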
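"""Hairpin folding and miRNA candidate calling.

Precursor detection follows the classic small-RNA annotation recipe: fold
genomic windows flanking a read stack, require a single long stem-loop, and
accept a candidate only when the read stack shows the hallmarks of Drosha/
Dicer processing -- sufficient depth, a star strand from the opposite arm of
the duplex, and a homogeneous (precisely processed) 5' end.

Folding is maximum base pairing (Nussinov-style dynamic programming) over
Watson-Crick plus G.U wobble pairs with a minimum hairpin loop of 3 nt.
Acceptance is structural, not energetic: a window qualifies as a precursor
when it contains one near-contiguous stem of at least ``min_stem_pairs``
pairs (bulges up to ``max_bulge`` nt between consecutive pairs, and
bulge-penalized so that only stacking-dominated stems count) with the
mature read lying entirely on one arm and mostly paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

# ---------------------------------------------------------------------------
# folding

_CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),
}

#: minimum number of unpaired bases in a hairpin loop
MIN_LOOP = 3

#: default thresholds for hairpin acceptance
MIN_STEM_PAIRS = 18
MAX_BULGE = 4
BULGE_PENALTY = 3.0
MIN_MATURE_PAIRED_FRAC = 0.60

#: candidate-calling defaults
WINDOW_LENGTHS = (120, 100, 80, 60)
WINDOW_PAD = 10
MIN_LOCUS_READS = 10          # criterion: > 10 reads at the locus
MIN_MODAL5P_FRAC = 0.90       # criterion: precise 5' ends
STAR_SLACK = 3                # nt of slack at each end of the duplex partner
KNOWN_MAX_MISMATCH = 1        # homology to a known mature miRNA
ARM_BALANCE_MAX_FOLD = 10.0


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def can_pair(a: str, b: str) -> bool:
    """True if two RNA bases can form a Watson-Crick or G.U pair."""
    return (a, b) in _CANONICAL_PAIRS


@dataclass
class FoldResult:
    """An optimal nested secondary structure for one sequence."""

    sequence: str
    pairs: list[tuple[int, int]]  # 1-based (i, j), i < j

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def dot_bracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j in self.pairs:
            s[i - 1] = "("
            s[j - 1] = ")"
        return "".join(s)


def fold_max_pairs(seq: str) -> FoldResult:
    """Fold ``seq`` by maximizing the number of nested base pairs.

    Watson-Crick and G.U pairs are allowed; hairpin loops must contain at
    least three unpaired bases (``j - i >= 4`` for any pair). Traceback is
    deterministic: at each interval the 5'-most base is paired to the
    smallest partner index achieving the optimum, in preference to leaving
    it unpaired.
    """
    rna = _to_rna(seq)
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    n = len(rna)
    if n == 0:
        raise ValueError("empty sequence")

    # pairable[i] lists k > i + MIN_LOOP that can pair with i (0-based)
    pairable: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for k in range(i + MIN_LOOP + 1, n):
            if can_pair(rna[i], rna[k]):
                pairable[i].append(k)

    # N[i][j] = max pairs in rna[i..j]; table over 0-based inclusive spans
    N = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]
            row_next = N[i + 1]
            for k in pairable[i]:
                if k > j:
                    break
                cand = 1 + (row_next[k - 1] if k - 1 >= i + 1 else 0) \
                         + (N[k + 1][j] if k + 1 <= j else 0)
                if cand > best:
                    best = cand
            N[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < MIN_LOOP + 1:
            continue
        target = N[i][j]
        if target == 0:
            continue
        paired = False
        for k in pairable[i]:
            if k > j:
                break
            left = N[i + 1][k - 1] if k - 1 >= i + 1 else 0
            right = N[k + 1][j] if k + 1 <= j else 0
            if 1 + left + right == target:
                pairs.append((i + 1, k + 1))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    pairs.sort()
    return FoldResult(sequence=rna, pairs=pairs)


# ---------------------------------------------------------------------------
# hairpin detection

@dataclass
class HairpinCall:
    """Verdict of the single-stem hairpin test for one fold + mature span."""

    is_hairpin: bool
    stem: list[tuple[int, int]] = field(default_factory=list)
    arm5: Optional[tuple[int, int]] = None  # 1-based inclusive spans
    arm3: Optional[tuple[int, int]] = None
    loop: Optional[tuple[int, int]] = None
    mature_arm: Optional[str] = None        # "5p" | "3p"
    mature_paired_frac: float = 0.0


def _stem_table(seq: str, max_bulge: int, bulge_penalty: float = BULGE_PENALTY):
    """DP over bulge-penalized stems anchored at each outer pair.

    A stem is a nested run of pairs; consecutive pairs may be separated by
    at most ``max_bulge`` unpaired bases on either side, and every bulged
    base costs ``bulge_penalty`` against the +1 of each pair. The penalty
    keeps stems stacking-dominated: in random sequence an extension across
    a bulge loses more than the pair gains, so spurious sprawling chains do
    not accumulate. Returns score and pair-count tables plus the traceback
    (0-based indices); the innermost pair always encloses a loop of at
    least MIN_LOOP bases.
    """
    n = len(seq)
    S = [[0.0] * n for _ in range(n)]   # best score of a stem anchored at (i, j)
    P = [[0] * n for _ in range(n)]     # pairs in that stem
    inner: dict[tuple[int, int], tuple[int, int]] = {}
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not can_pair(seq[i], seq[j]):
                continue
            best, best_p, arg = 0.0, 0, None
            for i2 in range(i + 1, min(i + max_bulge + 2, n)):
                for j2 in range(j - 1, max(j - max_bulge - 2, i2 + MIN_LOOP), -1):
                    if P[i2][j2] == 0:
                        continue
                    cost = bulge_penalty * ((i2 - i - 1) + (j - j2 - 1))
                    ext = S[i2][j2] - cost
                    if ext > best:
                        best, best_p, arg = ext, P[i2][j2], (i2, j2)
            S[i][j] = 1.0 + best
            P[i][j] = 1 + best_p
            if arg is not None:
                inner[(i, j)] = arg
    return S, P, inner


def detect_hairpin(
    fold: FoldResult,
    mature_span: tuple[int, int],
    *,
    min_stem_pairs: int = MIN_STEM_PAIRS,
    max_bulge: int = MAX_BULGE,
    min_paired_frac: float = MIN_MATURE_PAIRED_FRAC,
    bulge_penalty: float = BULGE_PENALTY,
) -> HairpinCall:
    """Test whether a folded window is a miRNA-like hairpin hosting
    ``mature_span``.

    ``mature_span`` is 1-based inclusive on the folded sequence. The verdict
    is true iff the window contains a stem — a single nested run of pairs
    with bulges of at most ``max_bulge`` nt between consecutive pairs — of
    at least ``min_stem_pairs`` pairs, with the mature span entirely on one
    arm and at least ``min_paired_frac`` of the mature bases paired within
    the stem. The stem is located by its own dynamic program over the
    window (maximum-pairing structures are not unique, so the search does
    not depend on any one traceback).
    """
    lo, hi = mature_span
    if lo < 1 or hi > len(fold.sequence) or lo > hi:
        raise ValueError(f"mature span {mature_span} outside folded window")

    seq = fold.sequence
    S, P, inner = _stem_table(seq, max_bulge, bulge_penalty)
    n = len(seq)
    candidates = [(P[i][j], S[i][j], i, j) for i in range(n)
                  for j in range(i + 1, n) if P[i][j] >= min_stem_pairs]
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    best: Optional[HairpinCall] = None
    best_key: tuple = ()
    for _, score, i, j in candidates:
        chain = []
        cur = (i, j)
        while True:
            chain.append((cur[0] + 1, cur[1] + 1))  # back to 1-based
            if cur not in inner:
                break
            cur = inner[cur]
        i_max = max(a for a, _ in chain)
        j_min = min(b for _, b in chain)
        arm5 = (chain[0][0], i_max)
        arm3 = (j_min, chain[0][1])
        loop = (i_max + 1, j_min - 1)
        if arm5[0] <= lo and hi <= arm5[1]:
            arm = "5p"
            paired_pos = {a for a, _ in chain}
        elif arm3[0] <= lo and hi <= arm3[1]:
            arm = "3p"
            paired_pos = {b for _, b in chain}
        else:
            continue
        frac = sum(1 for p in range(lo, hi + 1) if p in paired_pos) / (hi - lo + 1)
        if frac >= min_paired_frac:
            # among qualifying stems, keep the best-scoring (most stacked)
            key = (score, len(chain), frac)
            if best is None or key > best_key:
                best = HairpinCall(True, chain, arm5, arm3, loop, arm, frac)
                best_key = key
    return best if best is not None else HairpinCall(False)


def duplex_partner_span(
    stem: Sequence[tuple[int, int]], mature_span: tuple[int, int], mature_arm: str
) -> Optional[tuple[int, int]]:
    """Span (1-based inclusive) paired to the mature within the stem."""
    lo, hi = mature_span
    if mature_arm == "5p":
        partners = [j for i, j in stem if lo <= i <= hi]
    else:
        partners = [i for i, j in stem if lo <= j <= hi]
    if not partners:
        return None
    return (min(partners), max(partners))


def arm_balance(mature_count: float, star_count: float,
                max_fold: float = ARM_BALANCE_MAX_FOLD) -> bool:
    """True when both duplex arms are retained at comparable levels.

    Both strands count as retained when the star is observed at all and the
    two arms differ by less than ``max_fold`` (default 10-fold).
    """
    if star_count <= 0 or mature_count <= 0:
        return False
    hi = max(mature_count, star_count)
    lo = min(mature_count, star_count)
    return hi / lo < max_fold


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y)


def match_known(seq: str, known: Mapping[str, str],
                max_mismatch: int = KNOWN_MAX_MISMATCH) -> Optional[str]:
    """Name of a known mature miRNA within ``max_mismatch`` of ``seq``."""
    rna = _to_rna(seq)
    for name in sorted(known):
        ref = _to_rna(known[name])
        if len(ref) == len(rna) and hamming(ref, rna) <= max_mismatch:
            return name
    return None


# ---------------------------------------------------------------------------
# candidate calling over mapped read stacks

@dataclass
class MirnaRecord:
    """An annotated miRNA: mature/star sequences, locus and counts."""

    name: str
    mature: str                       # RNA alphabet
    arm: Optional[str]                # "5p" | "3p" | None when no hairpin
    star: Optional[str]
    star_counts: dict[str, int]
    precursor: Optional[tuple[str, int, int, str]]  # chrom, start, end (0-based half-open), strand
    counts: dict[str, int]            # per-sample counts of the mature stack
    status: str                       # known-homolog | novel | known-homolog-unmapped
    both_arms_retained: bool = False
    structure: Optional[str] = None   # dot-bracket of the precursor window
    precursor_seq: Optional[str] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTU", "TGCAA"))[::-1]


def _group_stacks(hits, merge_gap: int = 30):
    """Chain mapped-read hits into locus stacks per (chrom, strand).

    ``hits``: iterable of (chrom, start, strand, sequence, counts) with
    0-based starts on the forward strand. Hits whose intervals are within
    ``merge_gap`` nt join one stack, so a stack covers a whole precursor
    (both arms and the loop).
    """
    by_key: dict[tuple[str, str], list] = {}
    for chrom, start, strand, seq, counts in hits:
        by_key.setdefault((chrom, strand), []).append((start, start + len(seq), seq, counts))
    stacks = []
    for (chrom, strand), rows in sorted(by_key.items()):
        rows.sort()
        cur: list = []
        cur_end = None
        for start, end, seq, counts in rows:
            if cur and start > cur_end + merge_gap:
                stacks.append((chrom, strand, cur))
                cur = []
                cur_end = None
            cur.append((start, end, seq, counts))
            cur_end = end if cur_end is None else max(cur_end, end)
        if cur:
            stacks.append((chrom, strand, cur))
    return stacks


def call_candidates(
    mapped_reads,
    genome: Mapping[str, str],
    known_matures: Mapping[str, str],
    *,
    window_lengths: Sequence[int] = WINDOW_LENGTHS,
    pad: int = WINDOW_PAD,
    min_reads: int = MIN_LOCUS_READS,
    min_modal5p: float = MIN_MODAL5P_FRAC,
    star_slack: int = STAR_SLACK,
    min_stem_pairs: int = MIN_STEM_PAIRS,
) -> list[MirnaRecord]:
    """Call miRNA candidates from mapped (and unmapped) reads.

    ``mapped_reads`` is an iterable of objects with attributes ``sequence``,
    ``loci`` (list of (chrom, start, strand)), ``counts`` (sample -> count)
    and ``rna_class``. Reads classified as miRNA candidates are stacked per
    locus; each stack is folded in windows of 60/80/100/120 nt with the most
    abundant read placed on either arm. A novel candidate must satisfy all
    four criteria: hairpin precursor, more than ``min_reads`` reads, a star
    read from the opposite arm of the duplex, and a modal 5' end carrying at
    least ``min_modal5p`` of the mature-arm reads. Reads within one mismatch
    of a known mature miRNA are accepted as homologs without the star
    requirement; unmapped homologs are kept with no precursor.
    """
    records: list[MirnaRecord] = []
    hits = []
    unmapped = []
    for r in mapped_reads:
        if r.rna_class == "miRNA-candidate":
            for chrom, start, strand in r.loci:
                hits.append((chrom, start, strand, r.sequence, r.counts))
        elif r.rna_class == "unmapped":
            unmapped.append(r)

    novel_idx = 0
    for chrom, strand, rows in _group_stacks(hits):
        total = sum(sum(c.values()) for _, _, _, c in rows)
        # most abundant read is the putative mature; deterministic tie-break
        mature_row = max(rows, key=lambda t: (sum(t[3].values()), t[2]))
        m_start, m_end, m_seq, _ = mature_row
        chrom_seq = genome[chrom]

        # scan window configurations; the first one passing hairpin AND star
        # wins, falling back to the first hairpin-only configuration (known
        # homologs are accepted without a star)
        best_call = None   # (fold, call, window, local, star_seq, star_counts)
        fallback = None
        for W in window_lengths:
            for placement in ("5p", "3p"):
                if placement == "5p":
                    w_start = m_start - pad if strand == "+" else m_end + pad - W
                else:
                    w_start = m_end + pad - W if strand == "+" else m_start - pad
                w_start = max(0, min(w_start, len(chrom_seq) - W))
                w_end = w_start + W
                if w_end > len(chrom_seq) or not (w_start <= m_start and m_end <= w_end):
                    continue
                window = chrom_seq[w_start:w_end]
                if strand == "+":
                    local = (m_start - w_start + 1, m_end - w_start)
                    wseq = _to_rna(window)
                else:
                    wseq = _to_rna(_revcomp(window))
                    local = (w_end - m_end + 1, w_end - m_start)
                fold = fold_max_pairs(wseq)
                call = detect_hairpin(fold, local, min_stem_pairs=min_stem_pairs)
                if not call.is_hairpin:
                    continue
                s_seq, s_counts = detect_star(
                    call, local, rows, (w_start, w_end), strand, slack=star_slack)
                if s_seq is not None:
                    best_call = (fold, call, (w_start, w_end), local, s_seq, s_counts)
                    break
                if fallback is None:
                    fallback = (fold, call, (w_start, w_end), local, None, {})
            if best_call:
                break
        if best_call is None:
            best_call = fallback

        known_name = match_known(m_seq, known_matures)
        mature_counts = _stack_counts(rows, m_start, m_end)
        modal = _modal5p_fraction(rows, m_start, m_end, strand)

        if best_call:
            fold, call, (w_start, w_end), local, star_seq, star_counts = best_call
            precursor = (chrom, w_start, w_end, strand)
            structure = fold.dot_bracket()
            prec_seq = fold.sequence
            arm = call.mature_arm
        else:
            star_seq, star_counts = None, {}
            W = window_lengths[0]
            w_start = max(0, min(m_start - pad, len(chrom_seq) - W))
            precursor = (chrom, w_start, w_start + W, strand)
            structure = None
            prec_seq = None
            arm = None

        is_novel_ok = (
            best_call is not None
            and total > min_reads
            and star_seq is not None
            and modal >= min_modal5p
        )
        if known_name is not None:
            status = "known-homolog"
            name = known_name
        elif is_novel_ok:
            novel_idx += 1
            status = "novel"
            name = f"novel-{chrom}-{m_start}"
        else:
            continue

        rec = MirnaRecord(
            name=name,
            mature=_to_rna(m_seq),
            arm=arm,
            star=_to_rna(star_seq) if star_seq else None,
            star_counts=star_counts,
            precursor=precursor,
            counts=mature_counts,
            status=status,
            structure=structure,
            precursor_seq=prec_seq,
        )
        rec.both_arms_retained = arm_balance(rec.total, sum(star_counts.values()))
        records.append(rec)

    # homology rescue of unmapped reads against the known set: only miRNAs
    # absent from the mapped annotation are added, one record per known
    # name with the matching reads' counts pooled
    annotated = {r.name for r in records}
    rescued: dict[str, dict[str, int]] = {}
    for r in unmapped:
        name = match_known(r.sequence, known_matures)
        if name is None or name in annotated:
            continue
        pool = rescued.setdefault(name, {})
        for s, c in r.counts.items():
            pool[s] = pool.get(s, 0) + c
    for name in sorted(rescued):
        records.append(
            MirnaRecord(
                name=name,
                mature=_to_rna(known_matures[name]),
                arm=None,
                star=None,
                star_counts={},
                precursor=None,
                counts=rescued[name],
                status="known-homolog-unmapped",
            )
        )
    return records


def _stack_counts(rows, m_start: int, m_end: int) -> dict[str, int]:
    """Summed per-sample counts of reads overlapping the mature interval."""
    out: dict[str, int] = {}
    for start, end, _, counts in rows:
        if start < m_end and end > m_start:
            for s, c in counts.items():
                out[s] = out.get(s, 0) + c
    return out


def _modal5p_fraction(rows, m_start: int, m_end: int, strand: str) -> float:
    """Fraction of mature-arm reads sharing the modal 5' position."""
    tally: dict[int, int] = {}
    for start, end, _, counts in rows:
        if start < m_end and end > m_start:
            five = start if strand == "+" else end - 1
            tally[five] = tally.get(five, 0) + sum(counts.values())
    total = sum(tally.values())
    if total == 0:
        return 0.0
    return max(tally.values()) / total


def detect_star(
    call: HairpinCall,
    mature_local: tuple[int, int],
    rows,
    window: tuple[int, int],
    strand: str,
    *,
    slack: int = STAR_SLACK,
):
    """Find the star read for a folded locus.

    The star is the most abundant read lying on the opposite arm whose span
    matches the duplex partner of the mature to within ``slack`` nt at each
    end. Returns ``(sequence, per-sample counts)`` or ``(None, {})``.
    """
    if not call.is_hairpin or call.mature_arm is None:
        return None, {}
    partner = duplex_partner_span(call.stem, mature_local, call.mature_arm)
    if partner is None:
        return None, {}
    w_start, w_end = window
    best = None
    for start, end, seq, counts in rows:
        if strand == "+":
            local = (start - w_start + 1, end - w_start)
        else:
            local = (w_end - end + 1, w_end - start)
        if abs(local[0] - partner[0]) <= slack and abs(local[1] - partner[1]) <= slack:
            n = sum(counts.values())
            if best is None or n > best[0]:
                best = (n, seq, counts)
    if best is None:
        return None, {}
    _, seq, counts = best
    out_seq = seq if strand == "+" else seq
    return out_seq, dict(counts)
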
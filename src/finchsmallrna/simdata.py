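"""Synthetic genome, annotation and barcoded small-RNA read generator.

Every downstream stage of the pipeline is exercised against data with fully
known truth: hairpin loci embedded in a toy three-chromosome genome (one of
them ``chrZ``), a multi-tissue x two-sex sample grid with Z-linked 2:1
dosage plus one strongly male-biased locus, isomiR events (terminal length
variants, untemplated A/U tailing, site-specific internal substitutions at
a planted GGU motif) and uniform per-base sequencing error.

Default rates match what deep small-RNA libraries typically show: length
variants at 25% of miRNA reads with >80% of them 3' variants, untemplated
tailing around 15% with U outnumbering A about 2:1, and a per-base error
rate of 0.5%. The Z-linked loci are given a modest share of total
expression (most Z-linked miRNAs are minor members of the pool), so
per-library renormalization leaves their male:female ratio essentially at
the 2:1 copy-number expectation.

Planted precursors are designed stem-loops: a 22-nt mature arm, a duplex
partner carrying two single-base deletions (so the mature maps uniquely on
the forward strand), an 8-15 nt loop, and an 8-bp stem extension beyond the
duplex. Each design is validated by refolding before placement.
Coordinates are 0-based half-open in BED output and in memory.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ADAPTER3 = "TCGTATGCCGTCTTCTGCTTGT"   # constant region after the pentamer barcode
ADAPTER5 = "GUUCAGAGUUCUACAGUCCGACGAUC"  # 5' adapter (not sequenced into 36-nt reads)

_DNA = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

MATURE_LEN = 22
READ_LEN = 36


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Fractions are per-read class probabilities; ``depth_per_sample`` is the
    number of reads drawn for each (tissue, sex) library.
    """

    seed: int = 0
    genome_len: int = 200_000
    n_mirna_loci: int = 12
    n_z_loci: int = 3
    cluster_spec: Sequence[tuple[int, int]] = ((2, 3000),)
    tissues: Sequence[str] = ("brain", "heart", "liver", "muscle")
    sexes: Sequence[str] = ("M", "F")
    depth_per_sample: int = 12_000
    frac_len_variants: float = 0.25
    frac_3p_among_len_variants: float = 0.80
    frac_tailing: float = 0.15
    frac_tail_u: float = 2 / 3          # U:A ~ 2:1 among tails
    subst_site_rate: float = 0.08
    frac_star: float = 0.05
    frac_decoy_reads: float = 0.05
    seq_error_rate: float = 0.005
    male_bias_factor: float = 10.0
    z_dosage_factor: float = 2.0
    z_expression_weight: float = 0.2    # Z loci are a minor share of the pool
    tissue_profiles: Optional[dict[int, dict[str, float]]] = None
    read_len: int = READ_LEN

    @property
    def samples(self) -> list[str]:
        return [f"{t}_{s}" for t in self.tissues for s in self.sexes]

    def validate(self) -> None:
        fracs = {
            "frac_len_variants": self.frac_len_variants,
            "frac_3p_among_len_variants": self.frac_3p_among_len_variants,
            "frac_tailing": self.frac_tailing,
            "frac_tail_u": self.frac_tail_u,
            "subst_site_rate": self.subst_site_rate,
            "frac_star": self.frac_star,
            "frac_decoy_reads": self.frac_decoy_reads,
            "seq_error_rate": self.seq_error_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be > 0")
        if self.n_z_loci > self.n_mirna_loci:
            raise ValueError("n_z_loci cannot exceed n_mirna_loci")
        for n, spacing in self.cluster_spec:
            if spacing >= 10_000:
                raise ValueError("cluster spacing must be < 10,000 nt")
            if n < 2:
                raise ValueError("clusters need >= 2 members")
        if self.frac_star + self.frac_len_variants + self.frac_tailing + self.subst_site_rate > 1:
            raise ValueError("class fractions sum above 1")


@dataclass
class LocusTruth:
    name: str
    chrom: str
    start: int        # precursor start, 0-based
    end: int          # precursor end, half-open
    strand: str
    mature: str       # DNA, genome orientation
    mature_start: int
    mature_end: int
    arm: str          # "5p" | "3p"
    star: str         # DNA
    star_start: int
    star_end: int
    cluster_id: Optional[int]
    is_z: bool
    is_male_biased: bool
    ggu_pos: int      # 1-based start of GGT triplet on the mature


@dataclass
class SimGenome:
    cfg: SimConfig
    genome: dict[str, str]
    loci: list[LocusTruth]
    ncrna_decoys: list[tuple[str, int, int, str]]   # chrom, start, end, name
    repeat_decoys: list[tuple[str, int, int, str]]
    known_ncrna: dict[str, str]

    def locus_table(self) -> pd.DataFrame:
        rows = []
        for L in self.loci:
            rows.append({
                "name": L.name, "chrom": L.chrom, "start": L.start, "end": L.end,
                "strand": L.strand, "mature": to_rna(L.mature),
                "mature_start": L.mature_start, "mature_end": L.mature_end,
                "arm": L.arm, "star": to_rna(L.star), "cluster_id": L.cluster_id,
                "is_z": L.is_z, "is_male_biased": L.is_male_biased,
                "ggu_pos": L.ggu_pos,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome construction

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_DNA), size=n))


def _design_mature(rng: np.random.Generator) -> tuple[str, int]:
    """A 22-nt DNA mature sequence with a GGT motif planted internally."""
    seq = list(_random_seq(rng, MATURE_LEN))
    pos = int(rng.integers(8, 13))  # 1-based start of GGT; U at pos+2, well internal
    seq[pos - 1:pos + 2] = list("GGT")
    return "".join(seq), pos


STEM_EXT = 8  # the duplex extends past the mature, as real pre-miRNA stems do


def _design_precursor(rng: np.random.Generator, mature: str,
                      arm: str) -> tuple[str, int, int, int]:
    """Build a precursor stem-loop around ``mature``.

    Returns (precursor sequence, mature offset, star offset, star length)
    with offsets 0-based within the precursor. The non-mature arm carries
    two single-base deletions (small asymmetric bulges opposite mature
    positions 6 and 16) so the mature read maps uniquely on the forward
    strand; an extra ``STEM_EXT`` bp of perfect duplex beyond the
    mature/star duplex keeps the planted stem dominant over spurious
    foldings of the window.
    """
    partner = list(_revcomp(mature))
    for mpos in sorted((6, 16)):
        ppos = MATURE_LEN - mpos  # 0-based index opposite mature[mpos-1]
        del partner[ppos]
    partner_seq = "".join(partner)
    star_len = len(partner_seq)
    ext = _random_seq(rng, STEM_EXT - 1) + "G"  # revcomp starts with C
    loop_len = int(rng.integers(8, 16))
    loop = "CG" + _random_seq(rng, loop_len - 2)
    if arm == "5p":
        prec = ext + mature + loop + partner_seq + _revcomp(ext)
        return prec, STEM_EXT, STEM_EXT + len(mature) + loop_len, star_len
    prec = ext + partner_seq + loop + mature + _revcomp(ext)
    return prec, STEM_EXT + star_len + loop_len, STEM_EXT, star_len


def make_genome(cfg: SimConfig) -> SimGenome:
    """Generate the toy genome with planted hairpin loci and decoys."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    chrom_fracs = {"chr1": 0.4, "chr2": 0.3, "chrZ": 0.3}
    chrom_lens = {c: int(cfg.genome_len * f) for c, f in chrom_fracs.items()}
    genome = {c: list(_random_seq(rng, n)) for c, n in chrom_lens.items()}

    n_auto = cfg.n_mirna_loci - cfg.n_z_loci
    n_cluster_members = sum(n for n, _ in cfg.cluster_spec)
    if n_cluster_members > n_auto:
        raise ValueError("cluster members exceed autosomal locus budget")

    # design loci; a design is accepted only when its precursor passes the
    # hairpin test with the mature on the intended arm (some random matures
    # are self-complementary enough to fold in a competing register)
    from .hairpin import detect_hairpin, fold_max_pairs

    loci: list[LocusTruth] = []
    designs = []
    for i in range(cfg.n_mirna_loci):
        arm = "5p" if i % 2 == 0 else "3p"
        for _attempt in range(50):
            mature, ggu = _design_mature(rng)
            prec, m_off, s_off, star_len = _design_precursor(rng, mature, arm)
            call = detect_hairpin(fold_max_pairs(to_rna(prec)),
                                  (m_off + 1, m_off + MATURE_LEN))
            if call.is_hairpin and call.mature_arm == arm:
                break
        else:
            raise ValueError("could not design a foldable locus")
        designs.append((mature, ggu, arm, prec, m_off, s_off, star_len))

    # placement plan: clusters first on chr1, singles on chr1/chr2, Z loci on chrZ
    flank = 200
    placements: list[tuple[str, int, int, Optional[int]]] = []  # chrom, design idx, start, cluster

    def _place_run(chrom: str, idxs: list[int], spacing: int, cursor: int,
                   cluster: Optional[int]) -> int:
        for k, di in enumerate(idxs):
            start = cursor if k == 0 else placements[-1][2] + spacing
            prec = designs[di][3]
            if start + len(prec) + flank > chrom_lens[chrom]:
                raise ValueError("genome too short for requested loci")
            placements.append((chrom, di, start, cluster))
        return placements[-1][2] + len(designs[idxs[-1]][3]) + flank

    # singleton loci sit > 10 kb apart so they never chain into clusters
    single_gap = 11_000
    di = 0
    cursor = flank
    for ci, (n, spacing) in enumerate(cfg.cluster_spec):
        cursor = _place_run("chr1", list(range(di, di + n)), spacing, cursor, ci)
        di += n
    cursor2 = flank
    for j in range(di, n_auto):
        if (j - di) % 2 == 0:
            cursor2 = _place_run("chr2", [j], 0, cursor2, None) + single_gap
        else:
            cursor = _place_run("chr1", [j], 0, cursor + single_gap, None)
    cursorZ = flank
    for j in range(n_auto, cfg.n_mirna_loci):
        cursorZ = _place_run("chrZ", [j], 0, cursorZ, None) + single_gap

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for chrom, d, start, cluster in placements:
        mature, ggu, arm, prec, m_off, s_off, star_len = designs[d]
        end = start + len(prec)
        for a, b in occupied[chrom]:
            if start < b and end > a:
                raise ValueError("planted loci overlap")
        occupied[chrom].append((start, end))
        genome[chrom][start:end] = list(prec)
        # base right after the precursor must be untemplatable for A/U tails
        if end < chrom_lens[chrom]:
            genome[chrom][end] = "C"
        if end + 1 < chrom_lens[chrom]:
            genome[chrom][end + 1] = "G"
        is_z = chrom == "chrZ"
        idx = len(loci)
        star = prec[s_off:s_off + star_len]
        loci.append(LocusTruth(
            name=f"sim-mir-{d + 1}",
            chrom=chrom, start=start, end=end, strand="+",
            mature=mature,
            mature_start=start + m_off, mature_end=start + m_off + MATURE_LEN,
            arm=arm,
            star=star,
            star_start=start + s_off, star_end=start + s_off + star_len,
            cluster_id=cluster, is_z=is_z,
            is_male_biased=False, ggu_pos=ggu,
        ))
    # the last Z locus is the strongly male-biased one (miR-2954-like)
    z_loci = [L for L in loci if L.is_z]
    if z_loci:
        z_loci[-1].is_male_biased = True

    # decoy ncRNA (tRNA/rRNA stand-ins) and repeat intervals on chr2
    ncrna_decoys, repeat_decoys, known_ncrna = [], [], {}
    dec_cursor = chrom_lens["chr2"] - 3_000
    for k in range(4):
        length = int(rng.integers(70, 90))
        start = dec_cursor
        seq = _random_seq(rng, length)
        genome["chr2"][start:start + length] = list(seq)
        name = f"decoy-ncrna-{k + 1}"
        ncrna_decoys.append(("chr2", start, start + length, name))
        known_ncrna[name] = seq
        dec_cursor += length + 150
    rep_cursor = chrom_lens["chr1"] - 2_000
    for k in range(3):
        length = 200
        repeat_decoys.append(("chr1", rep_cursor, rep_cursor + length, f"decoy-repeat-{k + 1}"))
        rep_cursor += length + 150

    genome_str = {c: "".join(s) for c, s in genome.items()}
    for L in loci:
        assert genome_str[L.chrom][L.mature_start:L.mature_end] == L.mature
    return SimGenome(cfg=cfg, genome=genome_str, loci=loci,
                     ncrna_decoys=ncrna_decoys, repeat_decoys=repeat_decoys,
                     known_ncrna=known_ncrna)


# ---------------------------------------------------------------------------
# barcodes

def barcode_map(cfg: SimConfig) -> dict[str, str]:
    """Deterministic pentamer barcodes, pairwise Hamming distance >= 3."""
    chosen: list[str] = []
    out: dict[str, str] = {}
    samples = cfg.samples
    for cand in itertools.product(_DNA, repeat=5):
        bc = "".join(cand)
        if all(sum(a != b for a, b in zip(bc, c)) >= 3 for c in chosen):
            chosen.append(bc)
            if len(chosen) == len(samples):
                break
    if len(chosen) < len(samples):
        raise ValueError("cannot assign distinct barcodes to all samples")
    for bc, s in zip(chosen, samples):
        out[bc] = s
    return out


# ---------------------------------------------------------------------------
# read generation

_CLASSES = ("canonical", "len5", "len3", "tailU", "tailA", "subst", "star")


def _class_probs(cfg: SimConfig) -> dict[str, float]:
    p_len = cfg.frac_len_variants
    probs = {
        "star": cfg.frac_star,
        "len5": p_len * (1 - cfg.frac_3p_among_len_variants),
        "len3": p_len * cfg.frac_3p_among_len_variants,
        "tailU": cfg.frac_tailing * cfg.frac_tail_u,
        "tailA": cfg.frac_tailing * (1 - cfg.frac_tail_u),
        "subst": cfg.subst_site_rate,
    }
    probs["canonical"] = 1.0 - sum(probs.values())
    return probs


def _locus_weights(cfg: SimConfig, sim: SimGenome, tissue: str, sex: str) -> np.ndarray:
    w = np.zeros(len(sim.loci))
    profiles = cfg.tissue_profiles or {}
    default_profile = {t: 1.0 for t in cfg.tissues}
    # locus 0 is brain-enriched by default to exercise tissue-enrichment calls
    builtin = {0: {t: (0.97 if t == "brain" else 0.01) for t in cfg.tissues}}
    for i, L in enumerate(sim.loci):
        prof = profiles.get(i, builtin.get(i, default_profile))
        base = prof.get(tissue, 0.0)
        if L.is_z:
            base *= cfg.z_expression_weight
            if sex == "F":
                base /= cfg.male_bias_factor if L.is_male_biased else cfg.z_dosage_factor
        w[i] = base
    return w


def _make_insert(rng: np.random.Generator, cls: str, L: LocusTruth,
                 chrom_seq: str) -> tuple[str, int, str]:
    """Build one insert. Returns (insert DNA, subst position 1-based or 0, tail)."""
    m = L.mature
    if cls == "canonical":
        return m, 0, ""
    if cls == "star":
        return L.star, 0, ""
    if cls == "len5":
        d = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
        s = L.mature_start + d
        return chrom_seq[s:L.mature_end], 0, ""
    if cls == "len3":
        d = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
        e = L.mature_end + d
        return chrom_seq[L.mature_start:e], 0, ""
    if cls in ("tailU", "tailA"):
        base = "T" if cls == "tailU" else "A"
        n = 1 if rng.random() < 0.7 else 2
        tail = ""
        for k in range(n):
            templ = chrom_seq[L.mature_end + k] if L.mature_end + k < len(chrom_seq) else ""
            tail += base if base != templ else ("A" if base == "T" else "T")
        return m + tail, 0, tail
    if cls == "subst":
        pos = L.ggu_pos + 2  # the T of the GGT triplet, 1-based
        alts = [b for b in _DNA if b != m[pos - 1]]
        alt = alts[int(rng.integers(0, 3))]
        return m[:pos - 1] + alt + m[pos:], pos, ""
    raise ValueError(cls)


def make_reads(cfg: SimConfig, sim: SimGenome):
    """Draw barcoded reads for every sample.

    Returns ``(fastq_records, read_truth)`` where ``fastq_records`` is a list
    of (read id, 36-nt sequence, quality string) and ``read_truth`` a
    DataFrame with one row per emitted read.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    probs = _class_probs(cfg)
    class_names = list(probs)
    class_p = np.array([probs[c] for c in class_names])
    bmap = {s: bc for bc, s in barcode_map(cfg).items()}

    records = []
    truth_rows = []
    rid = 0
    for tissue in cfg.tissues:
        for sex in cfg.sexes:
            sample = f"{tissue}_{sex}"
            bc = bmap[sample]
            w = _locus_weights(cfg, sim, tissue, sex)
            if w.sum() == 0 and cfg.frac_decoy_reads == 0:
                continue
            decoy_w = 0.0
            if cfg.frac_decoy_reads > 0 and (sim.ncrna_decoys or sim.repeat_decoys):
                ref = w.sum() if w.sum() > 0 else 1.0
                if cfg.frac_decoy_reads >= 1.0:
                    w[:] = 0.0
                    decoy_w = ref
                else:
                    decoy_w = ref * cfg.frac_decoy_reads / (1 - cfg.frac_decoy_reads)
            full_w = np.append(w, decoy_w)
            if full_w.sum() == 0:
                continue
            draws = rng.multinomial(cfg.depth_per_sample, full_w / full_w.sum())
            for li, n_reads in enumerate(draws):
                if n_reads == 0:
                    continue
                if li == len(sim.loci):  # decoy pseudo-locus
                    for _ in range(int(n_reads)):
                        seq, src = _decoy_read(rng, sim)
                        records.append(_emit(rng, cfg, rid, seq, bc))
                        truth_rows.append({
                            "read_id": f"r{rid}", "sample": sample, "locus": src,
                            "klass": "decoy", "subst_pos": 0, "tail": "",
                            "insert": seq,
                        })
                        rid += 1
                    continue
                L = sim.loci[li]
                chrom_seq = sim.genome[L.chrom]
                classes = rng.choice(len(class_names), size=int(n_reads), p=class_p)
                for c in classes:
                    cls = class_names[c]
                    insert, pos, tail = _make_insert(rng, cls, L, chrom_seq)
                    records.append(_emit(rng, cfg, rid, insert, bc))
                    truth_rows.append({
                        "read_id": f"r{rid}", "sample": sample, "locus": L.name,
                        "klass": cls, "subst_pos": pos, "tail": tail,
                        "insert": insert,
                    })
                    rid += 1
    truth = pd.DataFrame(truth_rows, columns=[
        "read_id", "sample", "locus", "klass", "subst_pos", "tail", "insert"])
    return records, truth


def _decoy_read(rng: np.random.Generator, sim: SimGenome) -> tuple[str, str]:
    pools = [(c, s, e, n, "ncrna") for c, s, e, n in sim.ncrna_decoys] + \
            [(c, s, e, n, "repeat") for c, s, e, n in sim.repeat_decoys]
    chrom, s, e, name, _kind = pools[int(rng.integers(0, len(pools)))]
    length = int(rng.integers(20, 25))
    start = int(rng.integers(s, max(s + 1, e - length)))
    return sim.genome[chrom][start:start + length], name


def _emit(rng: np.random.Generator, cfg: SimConfig, rid: int,
          insert: str, barcode: str) -> tuple[str, str, str]:
    read = (insert + barcode + ADAPTER3)[:cfg.read_len]
    if cfg.seq_error_rate > 0:
        chars = list(read)
        errs = np.nonzero(rng.random(len(chars)) < cfg.seq_error_rate)[0]
        for i in errs:
            alts = [b for b in _DNA if b != chars[i]]
            chars[i] = alts[int(rng.integers(0, 3))]
        read = "".join(chars)
    return f"r{rid}", read, "I" * len(read)


# ---------------------------------------------------------------------------
# UTR and cross-species homolog sets

def make_utrs(cfg: SimConfig, sim: SimGenome, *, n_genes: int = 600,
              z_frac: float = 0.10, site_rate_z: float = 0.5,
              site_rate_auto: float = 0.08,
              utr_len: tuple[int, int] = (200, 600)) -> pd.DataFrame:
    """Random 3'UTR set with seed sites for the male-biased miRNA planted
    preferentially into chrZ genes (a dosage-compensation-like target bias).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    biased = [L for L in sim.loci if L.is_male_biased]
    site = ""
    if biased:
        seed = to_rna(biased[0].mature)[1:8]
        site = _revcomp(seed.replace("U", "T"))
    rows = []
    n_z = int(round(n_genes * z_frac))
    for g in range(n_genes):
        chrom = "chrZ" if g < n_z else ("chr1" if g % 2 else "chr2")
        length = int(rng.integers(utr_len[0], utr_len[1] + 1))
        seq = _random_seq(rng, length)
        rate = site_rate_z if chrom == "chrZ" else site_rate_auto
        if site and rng.random() < rate:
            pos = int(rng.integers(0, length - len(site)))
            seq = seq[:pos] + site + seq[pos + len(site):]
        rows.append({"gene": f"gene{g + 1}", "chrom": chrom, "utr": seq})
    return pd.DataFrame(rows)


#: per-locus conservation plan cycled over loci: which species carry a
#: full hairpin homolog of the mature sequence
SPECIES_GROUPS = {
    "chicken": "avian",
    "human": "mammal",
    "zebrafish": "vertebrate_other",
    "worm": "invertebrate",
}
_TIER_PLAN = (
    (),                                          # species-specific
    ("chicken",),                                # avian-specific
    ("chicken", "human"),                        # avian + mammal
    ("chicken", "human", "zebrafish"),           # vertebrate
    ("chicken", "human", "zebrafish", "worm"),   # pan-animal
)
_TIER_NAMES = ("species-specific", "avian-specific", "avian+mammal",
               "vertebrate", "pan-animal")


def make_species(cfg: SimConfig, sim: SimGenome, *, bg_len: int = 4000):
    """Synthetic per-species sequence sets with planned conservation tiers.

    Returns ``(species_seqs, truth_tiers)``: a dict species -> one long
    sequence with hairpin homologs embedded per the cyclic tier plan, and
    the planned tier name per locus.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    species_parts: dict[str, list[str]] = {s: [_random_seq(rng, bg_len)] for s in SPECIES_GROUPS}
    truth = {}
    for i, L in enumerate(sim.loci):
        plan = _TIER_PLAN[i % len(_TIER_PLAN)]
        truth[L.name] = _TIER_NAMES[i % len(_TIER_PLAN)]
        for sp in plan:
            prec, _, _, _ = _design_precursor(rng, L.mature, L.arm)
            species_parts[sp].append(prec + _random_seq(rng, 300))
    return {sp: "".join(parts) for sp, parts in species_parts.items()}, truth


# ---------------------------------------------------------------------------
# writers

def write_fasta(path: Path, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_bed(path: Path, rows: Sequence[tuple]) -> None:
    """BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def write_fastq(path: Path, records) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_all(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the complete synthetic dataset to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = make_genome(cfg)
    records, truth = make_reads(cfg, sim)
    paths = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(paths["genome"], sim.genome)

    paths["loci_bed"] = outdir / "loci.bed"
    write_bed(paths["loci_bed"],
              [(L.chrom, L.start, L.end, L.name, 0, L.strand) for L in sim.loci])

    paths["ncrna_bed"] = outdir / "ncrna.bed"
    write_bed(paths["ncrna_bed"],
              [(c, s, e, n, 0, "+") for c, s, e, n in sim.ncrna_decoys])
    paths["repeats_bed"] = outdir / "repeats.bed"
    write_bed(paths["repeats_bed"],
              [(c, s, e, n, 0, "+") for c, s, e, n in sim.repeat_decoys])

    paths["known_ncrna"] = outdir / "known_ncrna.fa"
    write_fasta(paths["known_ncrna"], sim.known_ncrna)

    # half the planted matures are "known" miRNAs (a miRBase stand-in);
    # the rest must be discovered de novo
    known = {f"tgu-{L.name}": to_rna(L.mature) for L in sim.loci[::2]}
    paths["known_matures"] = outdir / "known_matures.fa"
    write_fasta(paths["known_matures"], known)

    paths["fastq"] = outdir / "reads.fastq"
    write_fastq(paths["fastq"], records)

    paths["barcodes"] = outdir / "barcodes.tsv"
    bmap = barcode_map(cfg)
    with open(paths["barcodes"], "w") as fh:
        for bc in bmap:
            fh.write(f"{bc}\t{bmap[bc]}\n")

    paths["truth_loci"] = outdir / "truth_loci.tsv"
    sim.locus_table().to_csv(paths["truth_loci"], sep="\t", index=False)
    paths["truth_reads"] = outdir / "truth_reads.tsv"
    truth.to_csv(paths["truth_reads"], sep="\t", index=False)

    utrs = make_utrs(cfg, sim)
    paths["utrs"] = outdir / "utrs.fa"
    write_fasta(paths["utrs"], {f"{r.gene}|{r.chrom}": r.utr for r in utrs.itertuples()})

    species, tiers = make_species(cfg, sim)
    species_dir = outdir / "species"
    species_dir.mkdir(exist_ok=True)
    for sp, seq in species.items():
        p = species_dir / f"{sp}.fa"
        write_fasta(p, {sp: seq})
    paths["species_dir"] = species_dir
    paths["truth_tiers"] = outdir / "truth_tiers.tsv"
    pd.Series(tiers, name="tier").rename_axis("name").to_csv(
        paths["truth_tiers"], sep="\t")
    return paths
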
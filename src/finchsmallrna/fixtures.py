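"""Built-in printed datasets from the zebra finch small-RNA study.

Two small tables are shipped as machine-readable fixtures: the
brain-enriched miRNA read counts with their conservation flags in human,
mouse and *Aplysia* (``table1``), and the canonical sequences plus
GGU-motif substitution read counts and percentages (``table2``). Also
included are the repertoire-level tallies the study reports (repertoire
size, avian-specific and single-tissue-enriched counts, and the chicken
miR-2954 target counts) used by the summary arithmetic.
"""

from __future__ import annotations

import pandas as pd

_TABLE1 = [
    # mirna, total reads, reads in brain, human, mouse, aplysia
    ("miR-9",     357811, 354947, True,  True,  False),
    ("miR-124",   111628, 111170, True,  True,  True),
    ("miR-137",    28008,  27599, True,  True,  True),
    ("miR-153",    16599,  16188, True,  False, True),
    ("miR-212",     8361,   8168, False, False, False),
    ("miR-135a",    7451,   7053, False, False, False),
    ("miR-219",     7228,   7198, False, False, False),
    ("miR-132",     6496,   6172, False, False, False),
    ("miR-34b",     6401,   6322, False, False, True),
    ("miR-129",     5909,   5535, True,  False, False),
    ("miR-551",     4992,   4949, False, False, False),
    ("miR-218",     4221,   4024, True,  True,  False),
    ("miR-383",     3822,   3743, False, False, False),
    ("miR-34c",     3628,   3593, False, False, False),
    ("miR-460b",    1447,   1402, False, False, False),
    ("miR-458",     1013,    958, False, False, False),
    ("miR-138b",     386,    358, True,  True,  False),
    ("miR-1805",     306,    297, False, False, False),
    ("miR-489",      304,    285, False, False, False),
    ("miR-1803",     264,    261, False, False, False),
]

_TABLE2 = [
    # mirna, canonical sequence (RNA), modified reads, percentage
    ("tgu-let-7a",   "UGAGGUAGUAGGUUGUAUAGUU",   11500,  5.5),
    ("tgu-let-7b",   "UGAGGUAGUAGGUUGUGUGGUU",    1629,  6.7),
    ("tgu-let-7c",   "UGAGGUAGUAGGUUGUAUGGUU",    1556,  5.2),
    ("tgu-let-7d",   "AGAGGUAGUAGGUUGCAUAGUU",     395,  5.5),
    ("tgu-let-7e",   "UGAGGUAGUAGAUUGAAUAGUU",    3864,  5.2),
    ("tgu-let-7f",   "UGAGGUAGUAGAUUGUAUAGUU",   12490,  5.1),
    ("tgu-let-7i",   "UGAGGUAGUAGUUUGUGCUGUU",    3792,  8.2),
    ("tgu-miR-122",  "UGGAGUGUGACAAUGGUGUUUG",    6211, 14.0),
    ("tgu-miR-133b", "UUGGUCCCCUUCAACCAGCUAU",      18,  5.1),
    ("tgu-miR-140",  "ACCACAGGGUAGAACCACGGAC",     674,  5.0),
    ("tgu-miR-15a",  "UAGCAGCACAUAAUGGUUUGU",      382,  5.4),
    ("tgu-miR-15c",  "UAGCAGCACAUCAUGGUUUGU",      187,  5.4),
    ("tgu-miR-181b", "AACAUUCAUUGCUGUCGGUGGGU",    254,  6.2),
    ("tgu-miR-183",  "UAUGGCACUGGUAGAAUUCACU",       5,  5.1),
    ("tgu-miR-18a",  "UAAGGUGCAUCUAGUGCAGAUA",     228, 12.5),
    ("tgu-miR-18b",  "UAAGGUGCAUCUAGUGCAGUU",        7,  5.0),
    ("tgu-miR-196",  "UAGGUAGUUUCAUGUUGUUGGG",       8, 10.0),
    ("tgu-miR-221",  "AGCUACAUUGUCUGCUGGGUUUC",   2636,  6.4),
    ("tgu-miR-222",  "AGCUACAUCUGGCUACUGGGUCUC",  1413,  6.5),
    ("tgu-miR-2970", "GACAGUCAGCAGUUGGUCUGG",      219, 11.7),
    ("tgu-miR-363",  "AAUUGCACGGUAUCCAUCUGU",       83,  6.8),
    ("tgu-miR-383",  "CAGAUCAGAAGGUGAUUGUGGC",     101,  7.3),
    ("tgu-miR-456",  "CAGGCUGGUUAGAUGGUUGUC",       34,  7.8),
    ("tgu-miR-458",  "AUAGCUCUUGGAAUGGUUCUGC",      31,  5.1),
    ("tgu-miR-551",  "GCGACCCAUACUUGGUUUCAG",       69,  5.0),
]

#: repertoire-level printed tallies
REPERTOIRE = {
    "n_mirnas": 193,
    "n_avian_specific": 29,
    "n_zebra_finch_specific": 19,
    "n_single_tissue_enriched": 32,
    "n_brain_enriched": 20,
    "chicken_targets_total": 403,
    "chicken_targets_on_z": 70,
}


def table1() -> pd.DataFrame:
    """Brain-enriched miRNAs: read counts and conservation flags."""
    return pd.DataFrame(
        _TABLE1,
        columns=["mirna", "total_reads", "brain_reads", "human", "mouse", "aplysia"],
    )


def table2() -> pd.DataFrame:
    """miRNAs with substitutions at the GGU motif."""
    return pd.DataFrame(
        _TABLE2, columns=["mirna", "canonical", "modified_reads", "percentage"])


def table1_tissue_matrix() -> pd.DataFrame:
    """Table 1 recast as a two-tissue count matrix (brain vs all others)."""
    t = table1().set_index("mirna")
    return pd.DataFrame({
        "brain": t["brain_reads"],
        "other": t["total_reads"] - t["brain_reads"],
    })
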
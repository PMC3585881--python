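"""isomiR classification, substitution-site calling, motifs, tailing."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

import finchsmallrna as f
from finchsmallrna.isomir import (IsomirProfile, SubstitutionSite,
                                  build_profile, call_sites, classify_read,
                                  find_ggu_sites, information_content,
                                  motif_windows, tailing_summary)

CANON = "UGAGGUAGUAGGUUGUAUAGUU"
# genomic template: 6-nt flanks; base after the canonical is C (untemplatable)
TEMPLATE = "ACGUCA" + CANON + "CGGAAC"
OFF = 6


class TestClassifyRead:
    def test_exact_read_is_canonical(self):
        cls, _ = classify_read(CANON, CANON, TEMPLATE, OFF)
        assert cls == "canonical"

    def test_untemplated_u_addition(self):
        cls, det = classify_read(CANON + "U", CANON, TEMPLATE, OFF)
        assert cls == "untemplated-U"
        assert det["tail"] == "U"

    def test_templated_3p_extension_is_length_variant(self):
        cls, det = classify_read(CANON + "C", CANON, TEMPLATE, OFF)
        assert cls == "3p-length-variant"
        assert det["d3"] == 1

    def test_5p_shift_templated(self):
        # 5' terminus shifted 1 nt in the 3' direction (the miR-133a2 pattern)
        cls, det = classify_read(CANON[1:], CANON, TEMPLATE, OFF)
        assert cls == "5p-length-variant"
        assert det["d5"] == 1 and det["d3"] == 0

    def test_internal_substitution_position(self):
        read = CANON[:14] + "C" + CANON[15:]
        cls, det = classify_read(read, CANON, TEMPLATE, OFF)
        assert cls == "internal-substitution"
        assert det["internal"] == [(15, CANON[14], "C")]

    def test_tail_takes_precedence_over_length(self):
        read = CANON[2:] + "AA"  # trimmed 5' end plus untemplated AA
        cls, det = classify_read(read, CANON, TEMPLATE, OFF)
        assert cls == "untemplated-A"
        assert det["d5"] == 2

    def test_unalignable_read_unclassified(self):
        cls, _ = classify_read("GCGCGCGCGCGCGCGCGCGCG", CANON, TEMPLATE, OFF)
        assert cls == "unclassified"


class TestCallSites:
    def _profile(self, total, mm, pos, alt="G"):
        p = IsomirProfile("m", CANON)
        p.total = total
        p.subst["ACGU".index(alt), pos - 1] = mm
        return p

    def test_site_called_with_editing_flag(self):
        # A at position 15? use a position whose reference is A
        pos = CANON.index("A", 9) + 1
        p = self._profile(200, 18, pos, "G")
        (site,) = call_sites(p)
        assert site.position == pos
        assert site.rate == pytest.approx(0.09)
        assert site.putative_editing == (CANON[pos - 1] == "A")
        assert site.error_pvalue < 1e-6

    def test_rate_at_or_below_threshold_not_called(self):
        assert call_sites(self._profile(200, 10, 10)) == []   # 5% exactly
        assert call_sites(self._profile(100, 4, 10)) == []

    def test_low_total_not_called(self):
        assert call_sites(self._profile(90, 10, 10)) == []    # total <= 100

    def test_terminal_positions_never_called(self):
        p = self._profile(200, 50, 2)
        p.subst["ACGU".index("G"), len(CANON) - 2] = 50
        assert call_sites(p) == []

    def test_in_seed_flag(self):
        p = self._profile(200, 20, 5)
        (site,) = call_sites(p)
        assert site.in_seed


class TestMotifWindows:
    def test_mir122_ggu_site(self):
        canon = "UGGAGUGUGACAAUGGUGUUUG"
        site = SubstitutionSite("miR-122", 17, "U", {"C": 10}, 0.14,
                                True, False, False, 0.0)
        windows, flags, dropped = motif_windows([site], {"miR-122": canon})
        assert dropped == 0
        assert windows == [canon[14:20]]
        assert windows[0][:3] == "GGU"
        assert flags[("miR-122", 17)]

    def test_non_ggu_context(self):
        canon = "UGGAGUGUGACAAUGGUGUUUG"
        site = SubstitutionSite("m", 11, canon[10], {"G": 5}, 0.06,
                                False, False, False, 0.0)
        _, flags, _ = motif_windows([site], {"m": canon})
        assert not flags[("m", 11)]

    def test_insufficient_context_dropped(self):
        site = SubstitutionSite("m", 2, CANON[1], {"G": 5}, 0.06,
                                False, True, False, 0.0)
        windows, _, dropped = motif_windows([site], {"m": CANON})
        assert windows == [] and dropped == 1

    def test_ggu_scan_matches_string_positions(self):
        canon = "UGAGGUAGUAGGUUGUAUAGUU"
        assert find_ggu_sites(canon) == [6, 13]


class TestInformationContent:
    def test_closed_forms(self):
        ic, _ = information_content(["GA", "GC", "GG", "GU"])
        assert ic[0] == pytest.approx(2.0)   # monomorphic column
        assert ic[1] == pytest.approx(0.0)   # uniform column
        ic2, _ = information_content(["G", "G", "U", "U"])
        assert ic2[0] == pytest.approx(1.0)  # half/half

    def test_bounds_and_monomorphic_iff_two_bits(self):
        rng = np.random.default_rng(0)
        wins = ["".join(rng.choice(list("ACGU"), 6)) for _ in range(50)]
        ic, freqs = information_content(wins)
        assert np.all(ic >= 0) and np.all(ic <= 2)
        for i in range(6):
            assert (ic[i] == pytest.approx(2.0)) == (freqs[i].max() == 1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            information_content([])


def _single_locus_profiles(rate: float, seed: int = 7):
    cfg = f.SimConfig(seed=seed, n_mirna_loci=1, n_z_loci=0, cluster_spec=(),
                      depth_per_sample=1250, frac_decoy_reads=0.0,
                      subst_site_rate=rate)
    sim = f.make_genome(cfg)
    _, truth = f.make_reads(cfg, sim)
    L = sim.loci[0]
    chrom = sim.genome[L.chrom]
    template = chrom[L.start - 10:L.end + 10].replace("T", "U")
    off = L.mature_start - (L.start - 10)
    counts = truth.groupby("insert").size()
    prof = build_profile(L.name, L.mature.replace("T", "U"), template, off,
                         list(counts.items()))
    return prof, L


class TestThresholdSharpnessOnSimulation:
    def test_planted_site_recovered_at_8pct(self):
        prof, L = _single_locus_profiles(0.08)
        sites = call_sites(prof)
        planted = L.ggu_pos + 2
        assert planted in {s.position for s in sites}
        site = next(s for s in sites if s.position == planted)
        assert site.in_ggu

    def test_no_site_called_at_4pct(self):
        prof, L = _single_locus_profiles(0.04)
        assert call_sites(prof) == []

    def test_partition_property(self):
        prof, _ = _single_locus_profiles(0.08)
        assert sum(prof.class_counts.values()) == prof.total


class TestTailingSummary:
    def test_sim_u_to_a_ratio(self, sim_reads, sim_cfg):
        _, truth = sim_reads
        tails = truth[truth.klass.isin(["tailU", "tailA"])]
        n = len(tails)
        p_u = sim_cfg.frac_tail_u
        se = math.sqrt(p_u * (1 - p_u) / n)
        assert abs((tails.klass == "tailU").mean() - p_u) <= 3 * se

    def test_no_tailing_gives_empty_summary(self):
        prof = IsomirProfile("m", CANON)
        out = tailing_summary([prof], {"m": "5p"})
        assert out["n_u_mirnas"] == 0 and out["n_a_mirnas"] == 0

    def test_extended_ratio_reported(self):
        prof = IsomirProfile("m", CANON)
        prof.class_counts["untemplated-U"] = 700
        prof.class_counts["canonical"] = 100
        out = tailing_summary([prof], {"m": "3p"})
        assert out["extended_ratio"]["m"] == pytest.approx(7.0)
        assert out["arm_crosstab"][("U", "3p")] == 1
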
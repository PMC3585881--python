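"""Seed matching and chromosomal enrichment of predicted targets."""

from __future__ import annotations

import math
import random
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import finchsmallrna as f
from finchsmallrna.targets import (UtrRecord, chromosome_percent,
                                   fisher_enrichment, seed_match, seed_site,
                                   target_report)

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"


def hypergeom_tail_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) by direct summation of hypergeometric probabilities."""
    N, K, n = a + b + c + d, a + c, a + b
    total = Fraction(0)
    denom = math.comb(N, n)
    for k in range(a, min(K, n) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
    return float(total)


class TestSeedMatch:
    def test_let7a_site_is_reverse_complement_of_seed(self):
        assert seed_site(LET7A) == "CTACCTC"
        utrs = [UtrRecord("g1", "chr1", "AAAA" + "CTACCTC" + "GGGG" * 3)]
        assert seed_match(LET7A, utrs) == {"g1"}

    def test_short_utr_excluded(self):
        utrs = [UtrRecord("g1", "chr1", "CTACCTC0"[:8])]
        assert seed_match(LET7A, utrs) == set()

    def test_case_and_alphabet_invariance(self):
        utrs = [UtrRecord("g1", "chr1", "aaaacuaccucaaaa")]
        assert seed_match(LET7A, utrs) == {"g1"}
        assert seed_match(LET7A.replace("U", "T"), utrs) == {"g1"}

    def test_short_mature_errors(self):
        with pytest.raises(ValueError):
            seed_site("UGAGGU")

    def test_matches_bruteforce_scan(self):
        rng = random.Random(5)
        utrs = [UtrRecord(f"g{i}", "chr1",
                          "".join(rng.choice("ACGT") for _ in range(500)))
                for i in range(200)]
        site = seed_site(LET7A)
        expected = {u.gene for u in utrs
                    if any(u.utr[i:i + 7] == site
                           for i in range(len(u.utr) - 6))}
        assert seed_match(LET7A, utrs) == expected


class TestFisherEnrichment:
    def _utrs(self, n_chrom, n_total):
        return [UtrRecord(f"g{i}", "chrZ" if i < n_chrom else "chr1", "A" * 50)
                for i in range(n_total)]

    def test_proportional_targets_not_enriched(self):
        utrs = self._utrs(100, 1000)
        targets = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(100, 190)}
        res = fisher_enrichment(targets, utrs, "chrZ")
        assert res.p_value == pytest.approx(
            hypergeom_tail_bruteforce(10, 90, 90, 810), rel=1e-9)
        assert 0.4 < res.p_value < 0.7

    def test_small_table_exact_tail(self):
        # 2x2 [[3,7],[10,80]]
        utrs = self._utrs(13, 100)
        targets = {f"g{i}" for i in range(3)} | {f"g{i}" for i in range(13, 20)}
        res = fisher_enrichment(targets, utrs, "chrZ")
        assert res.table == ((3, 7), (10, 80))
        assert res.p_value == pytest.approx(
            hypergeom_tail_bruteforce(3, 7, 10, 80), rel=1e-9)

    def test_degenerate_no_chromosome_genes(self):
        utrs = self._utrs(0, 50)
        res = fisher_enrichment({"g1", "g2"}, utrs, "chrZ")
        assert res.p_value == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), [], "chrZ")

    def test_matches_bruteforce_on_random_tables(self):
        rng = random.Random(17)
        for _ in range(60):
            N = rng.randint(10, 200)
            K = rng.randint(1, N - 1)
            n = rng.randint(1, N - 1)
            a = rng.randint(max(0, n + K - N), min(K, n))
            b, c = n - a, K - a
            d = N - K - b
            utrs = self._utrs(K, N)
            targets = {f"g{i}" for i in range(a)} | \
                      {f"g{i}" for i in range(K, K + b)}
            res = fisher_enrichment(targets, utrs, "chrZ")
            assert res.table == ((a, b), (c, d))
            assert res.p_value == pytest.approx(
                hypergeom_tail_bruteforce(a, b, c, d), rel=1e-9, abs=1e-12)

    def test_agrees_with_scipy_fisher(self):
        # cross-check against the dedicated 2x2 implementation
        utrs = self._utrs(30, 300)
        targets = {f"g{i}" for i in range(15)} | {f"g{i}" for i in range(30, 60)}
        res = fisher_enrichment(targets, utrs, "chrZ")
        (a, b), (c, d) = res.table
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        assert res.p_value == pytest.approx(p, rel=1e-9)


class TestPlantedBias:
    def test_z_biased_planting_detected(self, sim_cfg, sim_genome):
        utrs_df = f.make_utrs(sim_cfg, sim_genome)
        utrs = [UtrRecord(r.gene, r.chrom, r.utr) for r in utrs_df.itertuples()]
        (mb,) = [L for L in sim_genome.loci if L.is_male_biased]
        targets = seed_match(mb.mature, utrs)
        assert len(targets) >= 30
        res = fisher_enrichment(targets, utrs, "chrZ")
        assert res.p_value < 0.01

    def test_unbiased_planting_yields_uniform_p(self, sim_cfg, sim_genome):
        # randomized PIT of the discrete exact test is U(0,1) under H0
        from dataclasses import replace
        (mb,) = [L for L in sim_genome.loci if L.is_male_biased]
        rng = np.random.default_rng(99)
        pit = []
        for rep in range(200):
            cfg = replace(sim_cfg, seed=10_000 + rep)
            utrs_df = f.make_utrs(cfg, sim_genome, site_rate_z=0.08,
                                  site_rate_auto=0.08)
            utrs = [UtrRecord(r.gene, r.chrom, r.utr)
                    for r in utrs_df.itertuples()]
            targets = seed_match(mb.mature, utrs)
            res = fisher_enrichment(targets, utrs, "chrZ")
            (a, b), (c, d) = res.table
            N, K, n = a + b + c + d, a + c, a + b
            pgt = stats.hypergeom.sf(a, N, K, n)
            peq = stats.hypergeom.pmf(a, N, K, n)
            pit.append(pgt + rng.random() * peq)
        assert stats.kstest(pit, "uniform").pvalue > 0.01


class TestTargetReport:
    def test_printed_chicken_percentage(self):
        assert chromosome_percent(70, 403) == 17.4

    def test_report_percentages_close(self):
        utrs = [UtrRecord(f"g{i}", ["chr1", "chr2", "chrZ"][i % 3], "A" * 50)
                for i in range(90)]
        targets = {f"g{i}" for i in range(0, 30)}
        rep = target_report(targets, utrs)
        assert rep["target_percent"].sum() == pytest.approx(100.0, abs=0.5)
        assert rep["gene_percent"].sum() == pytest.approx(100.0, abs=0.5)

    def test_empty_targets_empty_table(self):
        utrs = [UtrRecord("g1", "chr1", "A" * 50)]
        assert target_report(set(), utrs).empty
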
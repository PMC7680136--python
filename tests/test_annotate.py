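import numpy as np
import pytest

from palcat.annotate import (
    AnnotationError,
    EnrichmentResult,
    GwasSnp,
    RegionSet,
    gain_of_palindrome,
    gwas_enrichment,
    intersect_intervals,
    merge_intervals,
    palindromic_coverage,
    read_gwas,
    region_overlap_counts,
    subtract_intervals,
)
from palcat.detect import BaseComposition, DetectionParams, Palindrome, find_palindromes
from palcat.seqio import GenomeSequence
from palcat.synthdata import random_genome, toy_gwas_snps, uniform_snps


def pal(start, end, chrom="1"):
    return Palindrome(
        chrom=chrom, start=start, end=end, arm_mismatches=0, core_mismatches=0,
        composition=BaseComposition(end - start, 0, 0, 0),
    )


class TestIntervalAlgebra:
    def test_merge(self):
        assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]

    def test_intersect(self):
        assert intersect_intervals([(0, 10), (20, 30)], [(5, 25)]) == [(5, 10), (20, 25)]

    def test_subtract(self):
        assert subtract_intervals([(0, 30)], [(5, 10), (20, 40)]) == [(0, 5), (10, 20)]


class TestRegionOverlap:
    def test_one_bp_rule_and_abutment(self):
        regions = [RegionSet("exon", {"1": [(25, 60)]})]
        counts, _ = region_overlap_counts([pal(10, 30)], regions)
        assert counts["exon"] == 1
        counts, _ = region_overlap_counts([pal(10, 25)], regions)
        assert counts["exon"] == 0  # half-open abutment does not overlap

    def test_toy_fixture_hand_enumerated(self):
        regions = [
            RegionSet("exon", {"1": [(100, 200), (300, 400)]}),
            RegionSet("intron", {"1": [(150, 350)]}),
            RegionSet("upstream3k", {"1": [(0, 120)]}),
        ]
        pals = [pal(90, 110), pal(160, 180), pal(250, 260), pal(390, 410), pal(500, 520)]
        counts, frac = region_overlap_counts(pals, regions)
        assert counts["exon"] == 3  # 90-110, 160-180, 390-410
        assert counts["intron"] == 2  # 160-180, 250-260
        assert counts["upstream3k"] == 1
        # derived: intron minus exon = [200, 300)
        assert counts["intron_not_exon"] == 1  # only 250-260
        # upstream & exon = [100, 120); upstream-only = [0, 100)
        assert counts["upstream_and_exon"] == 1
        assert counts["upstream_only"] == 1
        assert frac["exon"] == pytest.approx(1.0)  # both exons touched
        assert frac["upstream3k"] == pytest.approx(1.0)

    def test_interval_tree_equals_quadratic_scan(self):
        rng = np.random.default_rng(3)
        iv = sorted((int(s), int(s) + int(l) + 1) for s, l in
                    zip(rng.integers(0, 900, 40), rng.integers(1, 30, 40)))
        pals = [pal(int(s), int(s) + 8) for s in rng.integers(0, 950, 60)]
        counts, _ = region_overlap_counts(pals, [RegionSet("r", {"1": iv})])
        merged = merge_intervals(iv)
        brute = sum(
            any(p.start < e and s < p.end for s, e in merged) for p in pals
        )
        assert counts["r"] == brute

    def test_unknown_chromosome_skipped(self):
        counts, _ = region_overlap_counts(
            [pal(0, 8, chrom="1")], [RegionSet("r", {"99": [(0, 10)]})]
        )
        assert counts["r"] == 0


class TestCoverage:
    def test_empty(self):
        assert palindromic_coverage([], 100) == 0.0

    def test_overlapping_union(self):
        assert palindromic_coverage([pal(0, 10), pal(5, 15)], 100) == pytest.approx(0.15)

    def test_zero_length_rejected(self):
        with pytest.raises(AnnotationError):
            palindromic_coverage([], 0)

    def test_matches_per_base_membership(self):
        seq = random_genome(2000, 0.5, seed=8)
        pals = find_palindromes(seq)
        cov = palindromic_coverage(pals, len(seq))
        member = np.zeros(len(seq), dtype=bool)
        for p in pals:
            member[p.start : p.end] = True
        assert cov == pytest.approx(member.mean())

    def test_order_and_split_invariance(self):
        a = [pal(0, 10), pal(5, 15), pal(40, 60)]
        b = [pal(40, 50), pal(45, 60), pal(0, 15)]
        assert palindromic_coverage(a, 100) == palindromic_coverage(b, 100)


class TestEnrichment:
    def test_toy_arithmetic(self):
        """coverage 0.1 and 5/10 SNP hits give fold exactly 5.0."""
        pals = [pal(0, 10)]
        snps = [GwasSnp(f"rs{i}", "1", pos) for i, pos in
                enumerate([1, 3, 5, 7, 9, 20, 30, 40, 50, 60])]
        res = gwas_enrichment(snps, pals, assessed_length=100)
        assert res.observed_probability == 0.5
        assert res.expected_probability == pytest.approx(0.1)
        assert res.fold == pytest.approx(5.0)

    def test_zero_hits(self):
        res = gwas_enrichment([GwasSnp("rs1", "1", 50)], [pal(0, 10)], 100)
        assert res.fold == 0.0

    def test_no_palindromic_bases_rejected(self):
        with pytest.raises(AnnotationError):
            gwas_enrichment([GwasSnp("rs1", "1", 50)], [], 100)

    def test_uniform_null_gives_fold_one(self):
        """SNPs placed uniformly on the genome give fold ~ 1 within 3
        binomial standard errors."""
        seq = random_genome(5000, 0.5, seed=21)
        pals = find_palindromes(seq)
        snps = uniform_snps(seq.name, len(seq), n=10_000, seed=22)
        res = gwas_enrichment(snps, pals, len(seq))
        p = res.expected_probability
        se = (p * (1 - p) / len(snps)) ** 0.5
        assert abs(res.observed_probability - p) <= 3 * se


class TestGwasIO:
    def test_minimal_dialect(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("rsid\tchrom\tpos\ttrait\trisk\nrs1\t1\t100\tT2D\tA\n")
        snps, skipped = read_gwas(f)
        assert skipped == 0 and snps[0].risk_allele == "A" and snps[0].pos == 100

    def test_catalog_dialect_skips_bad_rows(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text(
            "DISEASE/TRAIT\tCHR_ID\tCHR_POS\tSNPS\tSTRONGEST SNP-RISK ALLELE\n"
            "T2D\t1\t100\trs1\trs1-A\n"
            "obesity\t2\t\trs2\trs2-?\n"
            "asthma\t3;4\t5;6\trs3\trs3-C\n"
        )
        snps, skipped = read_gwas(f)
        assert len(snps) == 1 and skipped == 2
        assert snps[0].rsid == "rs1" and snps[0].trait == "T2D"


class TestGainOfPalindrome:
    PARAMS = DetectionParams()

    def make_ref(self, window):
        # spacer flanks guarantee the window is the only palindromic context
        return GenomeSequence("1", "AACC" * 10 + window + "AACC" * 10)

    def test_near_to_perfect(self):
        ref = self.make_ref("GACATGGC")  # near: 1 core mismatch
        snp = GwasSnp("rs1", "1", 40 + 7, trait="t", risk_allele="T")
        d = gain_of_palindrome(snp, ref, self.PARAMS)
        assert d["change"] == "NEAR_TO_PERFECT"
        assert d["post_spans"] == [(40, 48)]

    def test_lost(self):
        ref = self.make_ref("GACATGTC")
        snp = GwasSnp("rs1", "1", 40 + 5, risk_allele="A")  # break core pair T
        d = gain_of_palindrome(snp, ref, self.PARAMS)
        assert d["change"] in ("LOST", "PERFECT_TO_NEAR")
        # with pure-spacer flanks the near state survives (1 core mismatch)
        assert d["change"] == "PERFECT_TO_NEAR"

    def test_no_core_anywhere(self):
        ref = GenomeSequence("1", "AACC" * 20)
        snp = GwasSnp("rs1", "1", 40, risk_allele="G")
        assert gain_of_palindrome(snp, ref, self.PARAMS) is None

    def test_reference_allele_returns_none(self):
        ref = self.make_ref("GACATGTC")
        snp = GwasSnp("rs1", "1", 41, risk_allele=ref.bases[40])
        assert gain_of_palindrome(snp, ref, self.PARAMS) is None
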
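import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palcat.detect import (
    BaseComposition,
    DetectionError,
    DetectionParams,
    at_richness,
    extend_center,
    find_palindromes,
    is_near_palindrome_at,
    length_histogram,
    maximal_only,
    to_bed6,
)
from palcat.seqio import GenomeSequence, reverse_complement
from palcat.synthdata import random_genome

from _oracle import brute_force_spans


def gs(bases: str) -> GenomeSequence:
    return GenomeSequence(name="t", bases=bases)


class TestExtendCenter:
    def test_perfect_eight_mer(self, fig_example):
        p = extend_center(fig_example, 4)
        assert (p.start, p.end, p.length) == (0, 8, 8)
        assert p.arm_mismatches == 0 and p.core_mismatches == 0
        assert p.is_perfect and p.midpoint == 4

    def test_non_complementary_core_rejected(self):
        # A:A never pairs, so a homopolymer has 4 core mismatches
        assert extend_center(gs("AAAAAAAA"), 4) is None

    def test_extend_then_trim_to_complementary_edge(self):
        # extension takes two mismatched pairs (C,A) and (C,C) within budget;
        # both leave a mismatched edge, so trimming strips them again
        p = extend_center(gs("CCGACATGTCAC"), 6)
        assert (p.start, p.end) == (2, 10)
        assert p.arm_mismatches == 0 and p.core_mismatches == 0

    def test_mismatch_counts_recomputed_on_final_span(self):
        # interior arm mismatch survives trimming and is counted
        seq = gs("AT" + "GACATGTC" + "AT")  # AT flank pairs complement
        p = extend_center(seq, 6)
        assert (p.start, p.end) == (0, 12)
        assert p.arm_mismatches == 0

    def test_center_out_of_range(self, fig_example):
        with pytest.raises(DetectionError):
            extend_center(fig_example, 3)
        with pytest.raises(DetectionError):
            extend_center(fig_example, 5)

    def test_extension_stops_at_n(self):
        seq = gs("NTGACATGTCTA")
        p = extend_center(seq, 6)
        # pair (T,T) at k=5 mismatches; the N at k=6 stops extension anyway
        assert (p.start, p.end) == (2, 10)

    def test_core_with_n_rejected(self):
        assert extend_center(gs("GACNTGTC"), 4) is None


class TestFindPalindromes:
    def test_single_palindrome(self, fig_example):
        pals = find_palindromes(fig_example)
        assert len(pals) == 1 and pals[0].midpoint == 4

    def test_too_short_sequence(self):
        assert find_palindromes(gs("ACGTACG")) == []

    def test_distinct_centers_distinct_midpoints(self):
        seq = random_genome(500, 0.5, seed=5)
        pals = find_palindromes(seq)
        mids = [p.midpoint for p in pals]
        assert len(mids) == len(set(mids))
        assert pals == sorted(pals, key=lambda p: (p.start, p.length))


@pytest.mark.parametrize("gc", [0.2, 0.5, 0.8])
@pytest.mark.parametrize("budget", [(0, 4), (1, 4), (0, 0)])
def test_detector_equals_brute_force_oracle(gc, budget):
    """Seed-extend-trim output equals direct enumeration of per-center
    maximal windows on random sequences."""
    core_mm, arm_mm = budget
    params = DetectionParams(max_core_mismatches=core_mm, max_arm_mismatches=arm_mm)
    for seed in range(5):
        seq = random_genome(800, gc, seed=seed * 31 + int(gc * 10))
        got = [
            (p.start, p.end, p.arm_mismatches, p.core_mismatches)
            for p in find_palindromes(seq, params)
        ]
        exp = brute_force_spans(seq.bases, 8, core_mm, arm_mm)
        assert got == exp


def test_detector_handles_n_like_oracle():
    rng = np.random.default_rng(42)
    bases = list(random_genome(600, 0.5, seed=9).bases)
    for i in rng.integers(0, 600, size=30):
        bases[i] = "N"
    seq = gs("".join(bases))
    got = [(p.start, p.end) for p in find_palindromes(seq)]
    exp = [(s, e) for s, e, _a, _c in brute_force_spans(seq.bases)]
    assert got == exp


def test_strand_symmetry():
    """Spans on the reverse complement mirror the forward spans exactly,
    with identical lengths and mismatch counts."""
    seq = random_genome(1200, 0.4, seed=17)
    L = len(seq)
    fwd = find_palindromes(seq)
    rev = find_palindromes(gs(reverse_complement(seq.bases)))
    fwd_set = {(p.start, p.end, p.arm_mismatches, p.core_mismatches) for p in fwd}
    rev_set = {(L - p.end, L - p.start, p.arm_mismatches, p.core_mismatches) for p in rev}
    assert fwd_set == rev_set


def test_every_palindrome_is_maximal_and_valid():
    from palcat.seqio import is_complementary

    seq = random_genome(1500, 0.5, seed=23)
    s = seq.bases
    for p in find_palindromes(seq):
        assert p.length % 2 == 0 and p.length >= 8
        assert "N" not in p.sequence(seq)
        assert p.arm_mismatches <= 4 and p.core_mismatches == 0
        # complementary outermost pair
        assert is_complementary(s[p.start], s[p.end - 1])
        # maximality: one more pair exits bounds, mismatches the edge rule,
        # or would exceed the arm budget
        lo, hi = p.start - 1, p.end
        if lo >= 0 and hi < len(s):
            grown_ok = (
                is_complementary(s[lo], s[hi])
                and p.arm_mismatches <= 4
                and "N" not in (s[lo], s[hi])
            )
            assert not grown_ok


class TestNearPalindrome:
    def test_one_core_mismatch_tolerated(self):
        assert is_near_palindrome_at(gs("GACATGGC"), 4)

    def test_perfect_implies_near(self, fig_example):
        assert is_near_palindrome_at(fig_example, 4)

    def test_many_core_mismatches_rejected(self):
        assert not is_near_palindrome_at(gs("AAAAAAAA"), 4)

    def test_out_of_range_center_is_false(self, fig_example):
        assert not is_near_palindrome_at(fig_example, 0)


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATATATAT", 100.0), ("GACATGTC", 50.0), ("GGCC", 0.0)],
    )
    def test_at_richness(self, seq, expected):
        assert at_richness(BaseComposition.of(seq)) == expected

    def test_at_richness_strand_invariant(self):
        s = "GGATCCTA"
        assert at_richness(BaseComposition.of(s)) == at_richness(
            BaseComposition.of(reverse_complement(s))
        )

    def test_zero_denominator(self):
        with pytest.raises(DetectionError):
            at_richness(BaseComposition(0, 0, 0, 0))

    @given(st.text(alphabet="ACGT", min_size=1, max_size=64))
    @settings(derandomize=True)
    def test_at_plus_cg_is_100(self, s):
        comp = BaseComposition.of(s)
        cg = (comp.C + comp.G) * 100.0 / comp.total
        assert at_richness(comp) + cg == pytest.approx(100.0)


class TestHistogramAndExports:
    def test_single_bin(self, fig_example):
        pals = find_palindromes(fig_example)
        assert length_histogram(pals, [8, 20]) == [1]

    def test_empty(self):
        assert length_histogram([], [8, 20, 40]) == [0, 0]

    def test_unsorted_edges_rejected(self):
        with pytest.raises(DetectionError):
            length_histogram([], [20, 8])

    def test_planted_lengths_match_manifest(self):
        from palcat.synthdata import simulate_cohort

        sim = simulate_cohort(n_events=8, seed=3)
        pals = find_palindromes(sim.reference)
        expected = sorted(
            e.plant.expected_span[1] - e.plant.expected_span[0]
            for e in sim.effects
            if e.plant.is_perfect_plant
        )
        assert sorted(p.length for p in pals) == expected
        hist = length_histogram(pals, [8, 20, 40])
        assert sum(hist) == len(pals)

    def test_maximal_only_filters_nested(self, fig_example):
        pals = find_palindromes(gs("TTGACATGTCAA"))
        # nested centers may report shorter contained spans; the filter
        # keeps only spans not strictly contained in a longer one
        kept = maximal_only(pals)
        assert all(
            not any(q.start <= p.start and p.end <= q.end and q.length > p.length for q in kept)
            for p in kept
        )
        assert max(p.length for p in kept) == max(p.length for p in pals)

    def test_bed6_export(self, fig_example):
        pals = find_palindromes(fig_example)
        bed = to_bed6(pals)
        assert bed == "chrT\t0\t8\tpal:chrT:4\t8\t+\n"
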
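"""Seed-extend-trim detection of perfect and near DNA palindromes.

A DNA palindrome is an even-length sequence whose first half is the reverse
complement of its second half: folded at its midpoint, the two arms pair.
Detection seeds at every candidate midpoint, requires the central core
(default 8 bases) to be self-complementary within a core mismatch budget
(0 pairs for perfect, 1 for near), extends symmetrically outward while the
cumulative arm mismatch budget (default 4 pairs) holds, then trims mismatched
pairs from the edges so the reported span ends on a complementary pair.

Midpoints lie *between* bases, so all spans are even-length. N never pairs
(including with another N): extension stops at the first N and cores
containing N are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .seqio import GenomeSequence, is_complementary

DEFAULT_LENGTH_BIN_EDGES = (8, 20, 40, 50, 60, 80, 100, 150, 200, math.inf)


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    """Mismatch budgets for the seed-extend-trim detector.

    core_len
        length of the central seed core in bases (even, >= 2).
    max_core_mismatches
        mismatched pairs tolerated inside the core: 0 detects perfect
        palindromes, 1 detects near-palindromes.
    max_arm_mismatches
        cumulative mismatched pairs tolerated outside the core over the
        whole palindrome (pairs, not bases).
    min_report_len
        minimum span length to report; defaults to core_len.
    """

    core_len: int = 8
    max_core_mismatches: int = 0
    max_arm_mismatches: int = 4
    min_report_len: Optional[int] = None

    def __post_init__(self):
        if self.core_len < 2 or self.core_len % 2:
            raise DetectionError(f"core_len must be even and >= 2, got {self.core_len}")
        if self.max_core_mismatches < 0 or self.max_arm_mismatches < 0:
            raise DetectionError("mismatch budgets must be >= 0")
        if self.min_report_len is None:
            object.__setattr__(self, "min_report_len", self.core_len)

    @property
    def half_core(self) -> int:
        return self.core_len // 2

    def near(self) -> "DetectionParams":
        """The near-palindrome variant: 1 core mismatch allowed."""
        return replace(self, max_core_mismatches=max(1, self.max_core_mismatches))


PERFECT = DetectionParams()
NEAR = PERFECT.near()


@dataclass(frozen=True)
class BaseComposition:
    A: int
    T: int
    C: int
    G: int

    @classmethod
    def of(cls, seq: str) -> "BaseComposition":
        return cls(seq.count("A"), seq.count("T"), seq.count("C"), seq.count("G"))

    @property
    def total(self) -> int:
        return self.A + self.T + self.C + self.G


@dataclass(frozen=True)
class Palindrome:
    """A detected palindrome: 0-based half-open span on one chromosome."""

    chrom: str
    start: int
    end: int
    arm_mismatches: int
    core_mismatches: int
    composition: BaseComposition

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """The point between the two arms (a between-base coordinate)."""
        return self.start + self.length // 2

    @property
    def is_perfect(self) -> bool:
        return self.core_mismatches == 0

    def sequence(self, seq: GenomeSequence) -> str:
        return seq.bases[self.start : self.end]


def at_richness(comp: BaseComposition) -> float:
    """AT-richness percentage: (A+T) * 100 / (A+T+C+G), in [0, 100]."""
    if comp.total == 0:
        raise DetectionError("AT-richness undefined for empty composition")
    return (comp.A + comp.T) * 100.0 / comp.total


def extend_center(
    seq: GenomeSequence, center: int, params: DetectionParams = PERFECT
) -> Optional[Palindrome]:
    """Seed-extend-trim at one candidate midpoint; None if the core fails.

    The core occupies [center - core_len/2, center + core_len/2). Pair k
    (k = 1, 2, ...) is (base at center-k, base at center+k-1). Extension
    stops before the pair that would exceed the arm budget, at the sequence
    bounds, or at the first N; trailing mismatched pairs are then trimmed
    (never into the core) and mismatch counts are recomputed on the final
    span.
    """
    s = seq.bases
    n = len(s)
    h = params.half_core
    if center < h or center > n - h:
        raise DetectionError(
            f"center {center} out of range [{h}, {n - h}] for core_len {params.core_len}"
        )

    core_mm = 0
    for k in range(1, h + 1):
        a, b = s[center - k], s[center + k - 1]
        if a == "N" or b == "N":
            return None  # unknown base cannot seed a palindrome
        if not is_complementary(a, b):
            core_mm += 1
            if core_mm > params.max_core_mismatches:
                return None

    arm_mm = 0
    k = h
    while True:
        j = k + 1
        lo, hi = center - j, center + j - 1
        if lo < 0 or hi >= n:
            break
        a, b = s[lo], s[hi]
        if a == "N" or b == "N":
            break
        if not is_complementary(a, b):
            if arm_mm + 1 > params.max_arm_mismatches:
                break
            arm_mm += 1
        k = j

    # trim mismatched edge pairs, never into the core
    while k > h and not is_complementary(s[center - k], s[center + k - 1]):
        k -= 1

    length = 2 * k
    if length < params.min_report_len:
        return None

    # recompute mismatch counts on the final span
    arm_mm = sum(
        not is_complementary(s[center - j], s[center + j - 1])
        for j in range(h + 1, k + 1)
    )
    start, end = center - k, center + k
    span = s[start:end]
    return Palindrome(
        chrom=seq.name,
        start=start,
        end=end,
        arm_mismatches=arm_mm,
        core_mismatches=core_mm,
        composition=BaseComposition.of(span),
    )


def find_palindromes(
    seq: GenomeSequence, params: DetectionParams = PERFECT
) -> list[Palindrome]:
    """All palindromes of seq: extend_center at every admissible midpoint.

    Each center yields at most one palindrome; distinct centers have distinct
    midpoints. Output is sorted by (start, length).
    """
    h = params.half_core
    out = []
    for center in range(h, len(seq) - h + 1):
        p = extend_center(seq, center, params)
        if p is not None:
            out.append(p)
    out.sort(key=lambda p: (p.start, p.length))
    return out


def is_near_palindrome_at(
    seq: GenomeSequence, center: int, params: DetectionParams = PERFECT
) -> bool:
    """True iff a near-palindrome (1 core mismatch tolerated) of reportable
    length exists with its midpoint at `center`."""
    near = params.near()
    h = near.half_core
    if center < h or center > len(seq) - h:
        return False
    return extend_center(seq, center, near) is not None


def maximal_only(pals: Sequence[Palindrome]) -> list[Palindrome]:
    """Suppress palindromes whose span is wholly contained in a longer
    reported span (the optional de-duplicated view of nested centers)."""
    keep = []
    for p in pals:
        contained = any(
            q.start <= p.start and p.end <= q.end and q.length > p.length
            for q in pals
        )
        if not contained:
            keep.append(p)
    return keep


def length_histogram(
    pals: Iterable[Palindrome],
    bin_edges: Sequence[float] = DEFAULT_LENGTH_BIN_EDGES,
) -> list[int]:
    """Counts of palindrome lengths in half-open bins [e_i, e_{i+1})."""
    edges = list(bin_edges)
    if any(a >= b for a, b in zip(edges, edges[1:])):
        raise DetectionError("bin edges must be strictly increasing")
    counts = [0] * (len(edges) - 1)
    for p in pals:
        for i in range(len(counts)):
            if edges[i] <= p.length < edges[i + 1]:
                counts[i] += 1
                break
    return counts


TABLE_COLUMNS = (
    "chrom start end length midpoint arm_mismatches core_mismatches "
    "is_perfect at_richness sequence".split()
)


def palindrome_table(pals: Sequence[Palindrome], seq: GenomeSequence):
    """Palindromes as a pandas DataFrame in the standard column layout."""
    import pandas as pd

    rows = [
        (
            p.chrom,
            p.start,
            p.end,
            p.length,
            p.midpoint,
            p.arm_mismatches,
            p.core_mismatches,
            p.is_perfect,
            float(f"{at_richness(p.composition):.6g}"),
            p.sequence(seq),
        )
        for p in pals
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def to_bed6(pals: Sequence[Palindrome]) -> str:
    """BED6 export: name pal:<chrom>:<midpoint>, score = length capped at 1000."""
    lines = [
        f"{p.chrom}\t{p.start}\t{p.end}\tpal:{p.chrom}:{p.midpoint}"
        f"\t{min(p.length, 1000)}\t+"
        for p in pals
    ]
    return "\n".join(lines) + ("\n" if lines else "")
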
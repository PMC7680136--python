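"""Classify how each palindrome changed in a personal haplotype.

The personal genome's palindromes are mapped back to reference coordinates
by midpoint liftover. A personal palindrome whose mapped midpoint coincides
with a reference palindrome midpoint has remained intact (possibly shorter,
longer, or sequence-altered); a mapped midpoint with no reference palindrome
is a NEW palindrome unless the reference is a near-palindrome there
(NEAR_TO_PERFECT). Reference palindromes left unclaimed are tested at their
personal image: still near -> PERFECT_TO_NEAR, otherwise LOST. Palindromes
that lie wholly inside inserted sequence have no reference image and are
coded IN_INSERTION, keyed by the insertion's reference anchor plus an
ordinal so the same insertion shared across individuals yields stable keys.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .detect import DetectionParams, Palindrome, find_palindromes, is_near_palindrome_at
from .personal import IN_INSERTION as _IN_INS
from .personal import HaplotypeGenome
from .seqio import GenomeSequence


class ChangeCode(str, Enum):
    IDENTICAL = "IDENTICAL"
    SHORTER = "SHORTER"
    LONGER = "LONGER"
    SAME_LEN_CHANGED = "SAME_LEN_CHANGED"
    NEW = "NEW"
    LOST = "LOST"
    NEAR_TO_PERFECT = "NEAR_TO_PERFECT"
    PERFECT_TO_NEAR = "PERFECT_TO_NEAR"
    IN_INSERTION = "IN_INSERTION"


# individual-level code when the two haplotypes disagree (most disruptive wins)
PRECEDENCE = (
    ChangeCode.LOST,
    ChangeCode.PERFECT_TO_NEAR,
    ChangeCode.SHORTER,
    ChangeCode.LONGER,
    ChangeCode.SAME_LEN_CHANGED,
    ChangeCode.NEAR_TO_PERFECT,
    ChangeCode.NEW,
    ChangeCode.IN_INSERTION,
)


def make_key(chrom: str, midpoint: int) -> str:
    """Row key for a palindrome anchored at a reference midpoint."""
    return f"{chrom}:{midpoint}"


def make_insertion_key(chrom: str, anchor: int, ordinal: int) -> str:
    """Row key for a palindrome inside an insertion, anchored at the
    insertion's reference position with an ordinal for stability."""
    return f"{chrom}:ins{anchor}.{ordinal}"


def parse_key(key: str) -> tuple[str, int, int]:
    """(chrom, position, ordinal) sort triple; ordinal -1 for plain keys."""
    chrom, _, rest = key.rpartition(":")
    if rest.startswith("ins"):
        pos_s, _, ord_s = rest[3:].partition(".")
        return chrom, int(pos_s), int(ord_s)
    return chrom, int(rest), -1


@dataclass(frozen=True)
class PalindromeChange:
    """One (palindrome, sample, haplotype) classification."""

    key: str
    chrom: str
    sample: str
    haplotype: int
    code: ChangeCode
    ref_length: int = 0
    personal_length: int = 0


class ClassificationError(ValueError):
    pass


def classify_haplotype(
    ref_pals: Sequence[Palindrome],
    hap: HaplotypeGenome,
    ref: GenomeSequence,
    params: DetectionParams = DetectionParams(),
    personal_pals: Optional[Sequence[Palindrome]] = None,
) -> list[PalindromeChange]:
    """One change record per reference palindrome plus one per NEW or
    inserted personal palindrome.

    ref_pals must come from find_palindromes(ref, params); personal_pals may
    be passed to avoid recomputation, otherwise they are detected here with
    the same params.
    """
    if ref_pals and any(p.chrom != ref.name for p in ref_pals):
        raise ClassificationError("ref_pals chromosome does not match reference")
    if personal_pals is None:
        personal_pals = find_palindromes(hap.sequence, params)

    om = hap.offset_map
    by_mid = {p.midpoint: p for p in ref_pals}
    claimed: set[int] = set()
    changes: list[PalindromeChange] = []
    ins_counter: Counter[int] = Counter()

    for p in personal_pals:
        mapped = om.map_to_reference(p.midpoint)
        if mapped == _IN_INS:
            anchor = om.insertion_anchor(p.midpoint)
            ordinal = ins_counter[anchor]
            ins_counter[anchor] += 1
            changes.append(
                PalindromeChange(
                    key=make_insertion_key(ref.name, anchor, ordinal),
                    chrom=ref.name,
                    sample=hap.sample,
                    haplotype=hap.haplotype,
                    code=ChangeCode.IN_INSERTION,
                    ref_length=0,
                    personal_length=p.length,
                )
            )
            continue
        rp = by_mid.get(mapped)
        if rp is not None:
            claimed.add(mapped)
            if p.length == rp.length:
                same = p.sequence(hap.sequence) == rp.sequence(ref)
                code = ChangeCode.IDENTICAL if same else ChangeCode.SAME_LEN_CHANGED
            elif p.length < rp.length:
                code = ChangeCode.SHORTER
            else:
                code = ChangeCode.LONGER
            changes.append(
                PalindromeChange(
                    key=make_key(ref.name, mapped),
                    chrom=ref.name,
                    sample=hap.sample,
                    haplotype=hap.haplotype,
                    code=code,
                    ref_length=rp.length,
                    personal_length=p.length,
                )
            )
        else:
            # no reference palindrome here: near-palindrome rescue before NEW
            if is_near_palindrome_at(ref, mapped, params):
                code = ChangeCode.NEAR_TO_PERFECT
            else:
                code = ChangeCode.NEW
            changes.append(
                PalindromeChange(
                    key=make_key(ref.name, mapped),
                    chrom=ref.name,
                    sample=hap.sample,
                    haplotype=hap.haplotype,
                    code=code,
                    ref_length=0,
                    personal_length=p.length,
                )
            )

    for rp in ref_pals:
        if rp.midpoint in claimed:
            continue
        image = om.map_from_reference(rp.midpoint)
        if image is not None and is_near_palindrome_at(hap.sequence, image, params):
            code = ChangeCode.PERFECT_TO_NEAR
        else:
            # midpoint deleted, or no near-palindrome survives at the image
            code = ChangeCode.LOST
        changes.append(
            PalindromeChange(
                key=make_key(ref.name, rp.midpoint),
                chrom=ref.name,
                sample=hap.sample,
                haplotype=hap.haplotype,
                code=code,
                ref_length=rp.length,
                personal_length=0,
            )
        )

    changes.sort(key=lambda c: parse_key(c.key))
    _assert_unique_keys(changes)
    return changes


def _assert_unique_keys(changes: Sequence[PalindromeChange]) -> None:
    seen: set[str] = set()
    for c in changes:
        if c.key in seen:
            raise ClassificationError(f"duplicate change key {c.key}")
        seen.add(c.key)


@dataclass(frozen=True)
class IndividualChange:
    """Per-individual summary of the two haplotype codes at one key."""

    key: str
    chrom: str
    sample: str
    code: ChangeCode
    allele_count: int  # haplotypes carrying a non-IDENTICAL code (0..2)


def combine_haplotypes(
    changes0: Sequence[PalindromeChange], changes1: Sequence[PalindromeChange]
) -> list[IndividualChange]:
    """Merge the two haplotype change lists of one individual.

    A key missing from one haplotype (e.g. a NEW palindrome on the other) is
    treated as IDENTICAL there. When both haplotypes vary with different
    codes the most disruptive wins (LOST > PERFECT_TO_NEAR > SHORTER >
    LONGER > SAME_LEN_CHANGED > NEAR_TO_PERFECT > NEW > IN_INSERTION).
    """
    samples = {c.sample for c in changes0} | {c.sample for c in changes1}
    if len(samples) > 1:
        raise ClassificationError(f"haplotype lists mix samples: {sorted(samples)}")
    by_key: dict[str, list[PalindromeChange]] = {}
    chroms: dict[str, str] = {}
    for c in list(changes0) + list(changes1):
        by_key.setdefault(c.key, []).append(c)
        chroms[c.key] = c.chrom
    sample = next(iter(samples)) if samples else ""
    out = []
    for key in sorted(by_key, key=parse_key):
        codes = [c.code for c in by_key[key]]
        nonid = [c for c in codes if c != ChangeCode.IDENTICAL]
        if not nonid:
            code, ac = ChangeCode.IDENTICAL, 0
        else:
            uniq = set(nonid)
            if len(uniq) == 1:
                code = nonid[0]
            else:
                code = next(c for c in PRECEDENCE if c in uniq)
            ac = len(nonid)
        out.append(
            IndividualChange(
                key=key, chrom=chroms[key], sample=sample, code=code, allele_count=ac
            )
        )
    return out


def changes_table(changes: Sequence[PalindromeChange]):
    """Change list as a DataFrame (chrom, key, sample, haplotype, code,
    ref_length, personal_length)."""
    import pandas as pd

    return pd.DataFrame(
        [
            (c.chrom, c.key, c.sample, c.haplotype, c.code.value, c.ref_length, c.personal_length)
            for c in changes
        ],
        columns=["chrom", "key", "sample", "haplotype", "code", "ref_length", "personal_length"],
    )
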
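"""Personal haplotype genomes from phased VCF variants, with indel-aware
coordinate liftover.

Each individual contributes two haplotype sequences (palindromy is a property
of a single strand of one haplotype, so genotypes are never collapsed into
IUPAC codes). Applying insertions and deletions changes coordinates
downstream: a 2 bp insertion shifts every later personal position 2 to the
right of its reference image (cumulative offset -2), a 10 bp deletion shifts
them 10 to the left (offset +10). The OffsetMap records these cumulative
offsets so any personal position can be mapped back to the reference (and
vice versa) in O(log n).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .seqio import GenomeSequence, strip_chr

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


class VariantError(ValueError):
    pass


class VClass(str, Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"
    MNP = "MNP"


IN_INSERTION = "IN_INSERTION"


@dataclass(frozen=True)
class Variant:
    """A normalized small variant on one haplotype.

    pos is the 1-based reference position of the first affected base (VCF
    convention), after shared-prefix stripping: REF=AT, ALT=A at p becomes a
    deletion of T at p+1 with ref_allele="T", alt_allele="". A pure insertion
    correspondingly has an empty ref_allele; its pos names the reference base
    before which the alt bases are inserted.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        for a in (self.ref_allele, self.alt_allele):
            if set(a) - _ACGT:
                raise VariantError(f"non-ACGT allele {a!r} at {self.chrom}:{self.pos}")
        if not self.ref_allele and not self.alt_allele:
            raise VariantError(f"empty variant at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> VClass:
        lr, la = len(self.ref_allele), len(self.alt_allele)
        if lr == la == 1:
            return VClass.SNP
        if lr == la:
            return VClass.MNP
        return VClass.INS if la > lr else VClass.DEL

    @property
    def length_delta(self) -> int:
        """len(alt) - len(ref): positive for insertions."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def ref_start(self) -> int:
        """0-based start of the reference footprint."""
        return self.pos - 1

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.ref_allele)


def normalize_alleles(chrom: str, pos: int, ref: str, alt: str) -> Variant:
    """Strip the shared prefix of a VCF REF/ALT pair (anchor-base removal)."""
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    return Variant(chrom=chrom, pos=pos + k, ref_allele=ref[k:], alt_allele=alt[k:])


@dataclass
class OffsetMap:
    """Monotone personal-to-reference coordinate map induced by indels.

    Stored as collinear blocks (personal_start, ref_start, length) covering
    every personal position that has a reference image; gaps on the personal
    axis are insertion intervals, gaps on the reference axis are deletions.
    """

    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def breakpoints(self) -> list[tuple[int, int]]:
        """(personal_pos, cumulative_offset) at every offset change; the
        sentinel (0, 0) comes first (identity map when no indels)."""
        bps = [(0, 0)]
        for p, r, _l in self.blocks:
            off = r - p
            if off != bps[-1][1] or (p == 0 and len(bps) == 1):
                if (p, off) != bps[-1]:
                    bps.append((p, off))
        return bps

    @property
    def insertion_intervals(self) -> list[tuple[int, int]]:
        """Personal-coordinate half-open spans with no reference image."""
        out = []
        prev_end = 0
        for p, _r, l in self.blocks:
            if p > prev_end:
                out.append((prev_end, p))
            prev_end = p + l
        return out

    @property
    def final_offset(self) -> int:
        """Cumulative offset after the last variant; equals
        len(reference) - len(personal)."""
        if not self.blocks:
            return 0
        p, r, _l = self.blocks[-1]
        return r - p

    def map_to_reference(self, personal_pos: int):
        """Reference coordinate of a personal position, or IN_INSERTION."""
        if not self.blocks:
            raise VariantError("empty offset map")
        last_p, last_r, last_l = self.blocks[-1]
        if personal_pos < 0 or personal_pos >= last_p + last_l:
            raise VariantError(f"personal position {personal_pos} out of range")
        i = bisect.bisect_right(self._pstarts(), personal_pos) - 1
        if i < 0:
            return IN_INSERTION
        p, r, l = self.blocks[i]
        if personal_pos < p + l:
            return r + (personal_pos - p)
        return IN_INSERTION

    def map_from_reference(self, ref_pos: int) -> Optional[int]:
        """Personal coordinate of a reference position; None if deleted."""
        i = bisect.bisect_right(self._rstarts(), ref_pos) - 1
        if i < 0:
            return None
        p, r, l = self.blocks[i]
        if ref_pos < r + l:
            return p + (ref_pos - r)
        return None

    def insertion_anchor(self, personal_pos: int) -> int:
        """Reference position at which the insertion containing personal_pos
        is anchored (the ref coordinate of the following block)."""
        i = bisect.bisect_right(self._pstarts(), personal_pos)
        if i < len(self.blocks):
            return self.blocks[i][1]
        # insertion at the very end of the sequence
        p, r, l = self.blocks[-1]
        return r + l

    def _pstarts(self):
        return [b[0] for b in self.blocks]

    def _rstarts(self):
        return [b[1] for b in self.blocks]

    @classmethod
    def identity(cls, length: int) -> "OffsetMap":
        return cls(blocks=[(0, 0, length)])


@dataclass
class HaplotypeGenome:
    """One phased haplotype of one individual, with its liftover map."""

    sample: str
    haplotype: int
    sequence: GenomeSequence
    offset_map: OffsetMap
    applied: int = 0
    skipped: int = 0


def read_variants(
    path,
    sample: str,
    haplotype: int,
    *,
    unphased_policy: str = "error",
    region: Optional[str] = None,
) -> tuple[list[Variant], int]:
    """Read one haplotype's non-reference variants from a VCF.

    Returns (variants sorted by position, n_skipped). Symbolic alleles
    (<...>), breakends and spanning-deletion markers (*) are skipped and
    counted. Missing or half genotypes are treated as reference. Unphased
    heterozygotes follow `unphased_policy`: "error" (default) or "first"
    (deterministically take the GT field order with a warning).
    """
    from cyvcf2 import VCF

    if haplotype not in (0, 1):
        raise VariantError(f"haplotype must be 0 or 1, got {haplotype}")
    vcf = VCF(str(path), gts012=False)
    if sample not in vcf.samples:
        raise VariantError(f"sample {sample!r} not in VCF ({len(vcf.samples)} samples)")
    si = vcf.samples.index(sample)

    out: list[Variant] = []
    skipped = 0
    it = vcf(region) if region else vcf
    for rec in it:
        gt = rec.genotypes[si]  # [allele0, allele1, phased] (diploid)
        alleles = gt[:-1]
        phased = gt[-1]
        if len(alleles) == 1:  # haploid record
            alleles = [alleles[0], alleles[0]]
        a0, a1 = alleles[0], alleles[1]
        if not phased and a0 != a1 and a0 >= 0 and a1 >= 0:
            if unphased_policy == "error":
                raise VariantError(
                    f"unphased heterozygote for {sample} at {rec.CHROM}:{rec.POS}"
                )
            logger.warning(
                "unphased heterozygote at %s:%d assigned in GT order", rec.CHROM, rec.POS
            )
        ai = alleles[haplotype]
        if ai <= 0:  # reference, or missing (-1) treated as reference
            continue
        alt = rec.ALT[ai - 1]
        if (
            "<" in alt
            or "[" in alt
            or "]" in alt
            or alt == "*"
            or set(alt.upper()) - _ACGT
            or set(rec.REF.upper()) - _ACGT
        ):
            skipped += 1
            continue
        v = normalize_alleles(rec.CHROM, rec.POS, rec.REF.upper(), alt.upper())
        out.append(v)
    out.sort(key=lambda v: v.pos)
    return out, skipped


def build_haplotype(
    ref: GenomeSequence,
    variants: Sequence[Variant],
    sample: str = "sample",
    haplotype: int = 0,
    skipped: int = 0,
) -> HaplotypeGenome:
    """Apply sorted, non-overlapping variants to a reference sequence.

    Every ref_allele is checked against the reference (a mismatch usually
    means the wrong genome build); overlapping reference footprints are an
    error rather than silently resolved.
    """
    rbases = ref.bases
    pieces: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    cursor = 0  # reference coordinate
    ppos = 0  # personal coordinate
    prev = None
    for v in variants:
        if strip_chr(v.chrom) != strip_chr(ref.name):
            raise VariantError(f"variant on {v.chrom} applied to {ref.name}")
        if prev is not None and v.ref_start < prev.ref_end:
            raise VariantError(
                f"overlapping variants at {prev.chrom}:{prev.pos} and {v.chrom}:{v.pos}"
            )
        if v.ref_start < cursor or v.ref_end > len(rbases):
            raise VariantError(f"variant at {v.chrom}:{v.pos} out of order or bounds")
        seen = rbases[v.ref_start : v.ref_end]
        if seen != v.ref_allele:
            raise VariantError(
                f"REF mismatch at {v.chrom}:{v.pos}: VCF says {v.ref_allele!r}, "
                f"reference has {seen!r} (wrong build?)"
            )
        # collinear segment before the variant
        seg = rbases[cursor : v.ref_start]
        if seg:
            pieces.append(seg)
            blocks.append((ppos, cursor, len(seg)))
            ppos += len(seg)
        cursor = v.ref_start
        la, lr = len(v.alt_allele), len(v.ref_allele)
        if v.alt_allele:
            pieces.append(v.alt_allele)
        if la == lr:  # substitution: still collinear
            blocks.append((ppos, cursor, lr))
        elif lr == 0:
            pass  # pure insertion: personal gap, no block
        elif la == 0:
            pass  # pure deletion: reference gap, no block
        else:  # complex: align the leading min(la, lr) bases, rest is indel
            m = min(la, lr)
            blocks.append((ppos, cursor, m))
        ppos += la
        cursor += lr
        prev = v
    tail = rbases[cursor:]
    if tail:
        pieces.append(tail)
        blocks.append((ppos, cursor, len(tail)))
        ppos += len(tail)
        cursor += len(tail)
    # terminal sentinel so the map knows the personal length even when the
    # sequence ends in an insertion or deletion
    blocks.append((ppos, cursor, 0))

    personal = "".join(pieces)
    om = OffsetMap(blocks=_merge_blocks(blocks))
    hap = HaplotypeGenome(
        sample=sample,
        haplotype=haplotype,
        sequence=GenomeSequence(name=ref.name, bases=personal),
        offset_map=om,
        applied=len(variants),
        skipped=skipped,
    )
    assert len(ref) - len(personal) == om.final_offset
    return hap


def _merge_blocks(blocks: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    merged: list[tuple[int, int, int]] = []
    for p, r, l in blocks:
        if merged:
            mp, mr, ml = merged[-1]
            if mp + ml == p and mr + ml == r:
                merged[-1] = (mp, mr, ml + l)
                continue
        merged.append((p, r, l))
    return merged


def map_to_reference(om: OffsetMap, personal_pos: int):
    """Reference coordinate of a personal position, or IN_INSERTION."""
    return om.map_to_reference(personal_pos)


def write_offset_map(path, om: OffsetMap) -> None:
    """Serialize as tab-separated (personal_pos, cumulative_offset) rows plus
    insertion intervals prefixed with 'INS'."""
    with open(path, "w") as fh:
        for p, off in om.breakpoints:
            fh.write(f"{p}\t{off}\n")
        for s, e in om.insertion_intervals:
            fh.write(f"INS\t{s}\t{e}\n")
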
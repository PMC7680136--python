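"""Region annotation and GWAS-SNP enrichment for palindromes.

Palindromes are intersected with genomic region sets (exon, intron,
upstream3k, TFBS, CpG, ...) under the >=1 bp overlap rule, with derived
labels (intron minus exon, upstream-and-intron, upstream-and-exon,
upstream-only) computed by interval set algebra. Fold enrichment of GWAS
SNPs compares the observed fraction of SNPs falling inside palindromic
bases with the expected fraction under a uniform null, defined here as the
palindromic fraction of the assessed (non-N) bases.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .detect import DetectionParams, Palindrome, extend_center, find_palindromes
from .seqio import GenomeSequence, strip_chr

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass
class RegionSet:
    """Labeled genomic intervals (BED convention: 0-based half-open)."""

    label: str
    intervals: dict[str, list[tuple[int, int]]]  # chrom -> sorted spans

    def __post_init__(self):
        for chrom in self.intervals:
            self.intervals[chrom] = merge_intervals(self.intervals[chrom])

    @classmethod
    def from_bed(cls, label: str, path) -> "RegionSet":
        iv: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                iv.setdefault(strip_chr(f[0]), []).append((int(f[1]), int(f[2])))
        return cls(label=label, intervals=iv)


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open spans."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a, b) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    a, b = merge_intervals(a), merge_intervals(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a, b) -> list[tuple[int, int]]:
    """Set difference a \\ b on half-open spans."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


@dataclass(frozen=True)
class GwasSnp:
    rsid: str
    chrom: str
    pos: int  # 1-based
    trait: str = ""
    risk_allele: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise AnnotationError(f"{self.rsid}: position must be >= 1")
        if not self.rsid:
            raise AnnotationError("SNP without rsid")


def read_gwas(path) -> tuple[list[GwasSnp], int]:
    """Read GWAS associations from the GWAS Catalog TSV dialect (SNPS,
    CHR_ID, CHR_POS, DISEASE/TRAIT) or a minimal 4-column TSV
    (rsid, chrom, pos, trait[, risk_allele]). Returns (snps, n_skipped);
    rows with missing or multiple positions are skipped and counted."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.upper(): c for c in df.columns}
    if "SNPS" in cols:
        rsid_c, chrom_c, pos_c = cols["SNPS"], cols["CHR_ID"], cols["CHR_POS"]
        trait_c = cols.get("DISEASE/TRAIT")
        risk_c = cols.get("STRONGEST SNP-RISK ALLELE")
    else:
        rsid_c, chrom_c, pos_c = df.columns[0], df.columns[1], df.columns[2]
        trait_c = df.columns[3] if len(df.columns) > 3 else None
        risk_c = df.columns[4] if len(df.columns) > 4 else None
    snps, skipped = [], 0
    for _, row in df.iterrows():
        pos_s = row[pos_c]
        rsid = row[rsid_c]
        if pd.isna(pos_s) or pd.isna(rsid) or ";" in str(pos_s) or "x" in str(pos_s):
            skipped += 1
            continue
        try:
            pos = int(pos_s)
        except ValueError:
            skipped += 1
            continue
        risk = None
        if risk_c is not None and not pd.isna(row[risk_c]):
            token = str(row[risk_c]).rsplit("-", 1)[-1].strip()
            if token in {"A", "C", "G", "T"}:
                risk = token
        snps.append(
            GwasSnp(
                rsid=str(rsid),
                chrom=strip_chr(str(row[chrom_c])),
                pos=pos,
                trait="" if trait_c is None or pd.isna(row[trait_c]) else str(row[trait_c]),
                risk_allele=risk,
            )
        )
    return snps, skipped


def _pal_spans_by_chrom(pals: Sequence[Palindrome]) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {}
    for p in pals:
        spans.setdefault(strip_chr(p.chrom), []).append((p.start, p.end))
    return {c: merge_intervals(v) for c, v in spans.items()}


def region_overlap_counts(
    pals: Sequence[Palindrome], regions: Sequence[RegionSet]
) -> tuple[dict[str, int], dict[str, float]]:
    """Count palindromes overlapping each region label (>=1 bp rule), plus
    derived set-algebra labels, and the fraction of each label's intervals
    containing at least one palindrome.

    Derived labels (when the inputs are present): intron_not_exon,
    upstream_and_intron, upstream_and_exon, upstream_only.
    """
    by_label = {r.label: r for r in regions}
    derived: dict[str, dict[str, list[tuple[int, int]]]] = {}
    if "intron" in by_label and "exon" in by_label:
        derived["intron_not_exon"] = _algebra(by_label, "intron", "exon", subtract_intervals)
    if "upstream3k" in by_label and "intron" in by_label:
        derived["upstream_and_intron"] = _algebra(
            by_label, "upstream3k", "intron", intersect_intervals
        )
    if "upstream3k" in by_label and "exon" in by_label:
        derived["upstream_and_exon"] = _algebra(
            by_label, "upstream3k", "exon", intersect_intervals
        )
    if "upstream3k" in by_label:
        others: dict[str, list[tuple[int, int]]] = {}
        for lab in ("exon", "intron"):
            if lab in by_label:
                for c, iv in by_label[lab].intervals.items():
                    others.setdefault(c, []).extend(iv)
        up = by_label["upstream3k"].intervals
        derived["upstream_only"] = {
            c: subtract_intervals(iv, others.get(c, [])) for c, iv in up.items()
        }

    all_sets = {r.label: r.intervals for r in regions}
    all_sets.update(derived)

    trees = {
        lab: {c: IntervalTree.from_tuples(iv) for c, iv in ivs.items() if iv}
        for lab, ivs in all_sets.items()
    }
    counts = {lab: 0 for lab in all_sets}
    for p in pals:
        c = strip_chr(p.chrom)
        for lab, by_c in trees.items():
            tree = by_c.get(c)
            if tree is not None and tree.overlap(p.start, p.end):
                counts[lab] += 1

    pal_spans = _pal_spans_by_chrom(pals)
    frac_with_pal: dict[str, float] = {}
    for lab, ivs in all_sets.items():
        n_iv = sum(len(v) for v in ivs.values())
        if n_iv == 0:
            continue
        n_hit = 0
        for c, spans in ivs.items():
            psp = pal_spans.get(c, [])
            starts = [s for s, _e in psp]
            for s, e in spans:
                i = bisect.bisect_left(starts, e)
                if i > 0 and psp[i - 1][1] > s:
                    n_hit += 1
                elif i < len(psp) and psp[i][0] < e:
                    n_hit += 1
        frac_with_pal[lab] = n_hit / n_iv
    return counts, frac_with_pal


def _algebra(by_label, a, b, op):
    ia, ib = by_label[a].intervals, by_label[b].intervals
    return {c: op(iv, ib.get(c, [])) for c, iv in ia.items()}


def palindromic_coverage(pals: Sequence[Palindrome], assessed_length: int) -> float:
    """Fraction of assessed bases covered by >=1 palindrome span."""
    if assessed_length <= 0:
        raise AnnotationError("assessed_length must be > 0")
    covered = sum(
        e - s for spans in _pal_spans_by_chrom(pals).values() for s, e in spans
    )
    return covered / assessed_length


@dataclass(frozen=True)
class EnrichmentResult:
    n_snps_total: int
    n_snps_in_palindromes: int
    observed_probability: float
    expected_probability: float
    fold: float
    null_model: str = "palindromic fraction of assessed non-N bases"


def gwas_enrichment(
    snps: Sequence[GwasSnp], pals: Sequence[Palindrome], assessed_length: int
) -> EnrichmentResult:
    """Observed vs expected probability of SNPs in palindromic bases.

    observed = fraction of SNPs whose (0-based) position lies in a palindrome
    span; expected = palindromic_coverage; fold = observed / expected.
    """
    if not snps:
        raise AnnotationError("no SNPs to assess")
    expected = palindromic_coverage(pals, assessed_length)
    if expected == 0:
        raise AnnotationError("expected probability is 0: no palindromic bases")
    spans = _pal_spans_by_chrom(pals)
    n_in = 0
    for snp in snps:
        psp = spans.get(strip_chr(snp.chrom), [])
        pos0 = snp.pos - 1
        i = bisect.bisect_right([s for s, _e in psp], pos0) - 1
        if i >= 0 and psp[i][0] <= pos0 < psp[i][1]:
            n_in += 1
    observed = n_in / len(snps)
    return EnrichmentResult(
        n_snps_total=len(snps),
        n_snps_in_palindromes=n_in,
        observed_probability=observed,
        expected_probability=expected,
        fold=observed / expected,
    )


def gain_of_palindrome(
    snp: GwasSnp,
    ref: GenomeSequence,
    params: DetectionParams = DetectionParams(),
    probe: int = 60,
) -> Optional[dict]:
    """Effect of substituting the SNP's risk allele on local palindromes.

    Scans the +/-(core_len/2 + probe) window around the SNP before and after
    substitution for perfect palindromes covering the SNP position. Returns a
    descriptor dict (change, pre/post state and spans, window) or None when
    the local palindrome state is unchanged.

    change is NEW_PERFECT (none -> perfect, reference not even near),
    NEAR_TO_PERFECT (near -> perfect), PERFECT_TO_NEAR, LOST, LONGER or
    SHORTER.
    """
    if snp.risk_allele is None:
        raise AnnotationError(f"{snp.rsid}: no risk allele")
    pos0 = snp.pos - 1
    if not (0 <= pos0 < len(ref)):
        raise AnnotationError(f"{snp.rsid}: position outside reference")
    if ref.bases[pos0] == snp.risk_allele:
        logger.warning("%s: risk allele equals reference base", snp.rsid)
        return None
    w = params.half_core + probe
    ws, we = max(0, pos0 - w), min(len(ref), pos0 + w)
    pre_win = GenomeSequence(name=ref.name, bases=ref.bases[ws:we])
    post_bases = ref.bases[ws:pos0] + snp.risk_allele + ref.bases[pos0 + 1 : we]
    post_win = GenomeSequence(name=ref.name, bases=post_bases)
    local = pos0 - ws

    def covering(win: GenomeSequence) -> list[Palindrome]:
        return [p for p in find_palindromes(win, params) if p.start <= local < p.end]

    pre, post = covering(pre_win), covering(post_win)

    def near_at(win: GenomeSequence, centers: Iterable[int]) -> bool:
        np_ = params.near()
        h = np_.half_core
        for c in centers:
            if h <= c <= len(win) - h and extend_center(win, c, np_) is not None:
                return True
        return False

    result: Optional[str] = None
    if post and not pre:
        centers = [p.midpoint for p in post]
        result = "NEAR_TO_PERFECT" if near_at(pre_win, centers) else "NEW_PERFECT"
    elif pre and not post:
        centers = [p.midpoint for p in pre]
        result = "PERFECT_TO_NEAR" if near_at(post_win, centers) else "LOST"
    elif pre and post:
        lpre = max(p.length for p in pre)
        lpost = max(p.length for p in post)
        if lpost > lpre:
            result = "LONGER"
        elif lpost < lpre:
            result = "SHORTER"
    if result is None:
        return None
    return {
        "rsid": snp.rsid,
        "trait": snp.trait,
        "change": result,
        "pre_spans": [(p.start + ws, p.end + ws) for p in pre],
        "post_spans": [(p.start + ws, p.end + ws) for p in post],
        "window": (ws, we),
    }
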
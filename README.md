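# palcat — DNA palindromes in reference and personal genomes

`palcat` detects perfect and near DNA palindromes in genome sequences,
reconstructs personal haplotype genomes from phased VCF variants, classifies
how each palindrome changed in each individual, and aggregates the results
into a population-scale variation catalog with region annotation and
GWAS-SNP enrichment. It is aimed at researchers studying palindromic /
inverted-repeat loci — cruciform-forming sequences, PATRRs, palindromic
transcription-factor binding sites — and their variation across cohorts such
as the 1000 Genomes panel.

## The model

A DNA **palindrome** is an even-length sequence whose first half is followed
by its reverse complement: 5′-GACA|TGTC-3′ reads identically on both strands
and can fold at its midpoint into a hairpin or cruciform. Detection is
seed-extend-trim:

* **seed**: the central core of 8 bases around a candidate midpoint must be
  self-complementary, pairing base *c−k* with base *c+k−1* for k = 1…4
  (perfect: 0 mismatched pairs; *near*-palindrome: ≤ 1);
* **extend**: the span grows symmetrically (same length on both arms) while
  the cumulative number of mismatched pairs outside the core stays ≤ 4,
  stopping at sequence bounds or the first N;
* **trim**: mismatched pairs at the edges are deleted so every reported
  span ends on a complementary pair; mismatch counts are recomputed on the
  final span.

Personal genomes are built per haplotype by applying phased SNPs, insertions
and deletions to the reference. Indels shift coordinates: an insertion of
*L* bp introduces a cumulative offset of −*L* downstream, a deletion of *L*
bp an offset of +*L*; the offset at any position is the sum over all
variants before it. Mapping a personal palindrome's midpoint back through
this offset map and comparing with reference palindrome midpoints yields one
change code per palindrome and haplotype: `IDENTICAL`, `SHORTER`, `LONGER`,
`SAME_LEN_CHANGED`, `NEW`, `LOST`, `NEAR_TO_PERFECT`, `PERFECT_TO_NEAR`, or
`IN_INSERTION`. Codes are combined across the two haplotypes and assembled
into a palindrome × individual matrix from which conservation bins and
per-population profiles are computed.

AT-richness of a palindrome is (A+T)·100 / (A+T+C+G); GWAS-SNP fold
enrichment is the observed fraction of SNPs in palindromic bases divided by
the palindromic fraction of the assessed (non-N) bases.

## Worked example

```sh
$ printf '>chrT\nGACATGTC\n' > toy.fa
$ palcat find toy.fa -o pals.tsv
$ cat pals.tsv
chrom  start  end  length  midpoint  arm_mismatches  core_mismatches  is_perfect  at_richness  sequence
chrT   0      8    8       4         0               0                True        50.0         GACATGTC
```

The single row says: `GACATGTC` is one perfect palindrome spanning
positions [0, 8) with its midpoint between bases 3 and 4, no mismatched
pairs in core or arms, and AT-richness 50% (2 A + 2 T of 8 bases).

A full synthetic pipeline (simulate a cohort with a known truth manifest,
detect, classify, catalog):

```sh
palcat simulate --n-events 10 --seed 11 -o sim/
palcat find sim/reference.fa -o pals.tsv --maximal-only
palcat classify sim/reference.fa sim/cohort.vcf -o changes/ \
    $(awk 'NR>1{printf " -s %s", $1}' sim/panel.tsv)
palcat catalog changes/ sim/panel.tsv -o cat/
```

`cat/summary.json` then contains the conservation bins (fraction of
palindromes varying in 1, 2–5, 5–25, … individuals) and per-population
change-code profiles.

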
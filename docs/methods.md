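# Methods

## Palindrome model and detection

A palindrome is an even-length span whose arms pair under Watson–Crick
complementarity across the midpoint; midpoints lie *between* bases, so
odd-length spans do not exist in the model. Detection seeds at every
admissible midpoint: the central core (`core_len`, default 8 bases, even)
is checked pairwise; a candidate survives with at most
`max_core_mismatches` mismatched pairs (0 = perfect, 1 = near). The span
then extends one pair at a time, equally on both arms, while the cumulative
number of mismatched pairs outside the core is at most
`max_arm_mismatches` (default 4, counted as pairs over the whole palindrome,
not per arm — mismatches occur as pairs, and a per-arm reading would double
the budget). Extension halts before the pair that would exceed the budget,
at the sequence bounds, or at the first N. Finally, mismatched pairs are
trimmed from the edges — one pair at a time, while the current outermost
pair is mismatched, never into the core — so every reported span ends on a
complementary pair; mismatch counts are recomputed on the trimmed span.

Consequences of these rules, relied on throughout:

* The reported span per center equals the *largest* even window centered
  there that satisfies all invariants (no N, budgets, complementary edge).
  This is what the brute-force oracle in the tests enumerates directly.
* Every admissible center is reported independently; nested spans are not
  merged. A `--maximal-only` filter (drop spans wholly contained in longer
  ones) is available but off by default, since genome-wide totals depend on
  this counting convention and both views are legitimate.
* N is unknown, not a wildcard: it never pairs (not even with N), cores
  containing N are rejected, extension stops at the first N.
* A near-palindrome query (`is_near_palindrome_at`) is simply detection
  with the core budget raised to 1 at a fixed midpoint.

AT-richness is (A+T)·100/(A+T+C+G) over the span; spans with ≥ 50 are
called AT-rich. Output ordering is (chrom, start, length), deterministic
regardless of scan strategy.

## Personal genomes and liftover

Each individual contributes two haplotype sequences; genotypes are never
collapsed into IUPAC ambiguity codes because palindromy is a property of one
strand of one haplotype. Variants are read per haplotype from phased VCF
(cyvcf2), resolving multi-allelic records through the GT index, skipping and
counting symbolic/SV/`*` alleles, treating missing or half genotypes as
reference, and normalizing shared REF/ALT prefixes (REF=AT, ALT=A at p
becomes a deletion of T at p+1 — after stripping, a pure insertion has an
empty reference allele and a pure deletion an empty alternate). Unphased
heterozygotes are an error by default (policy `first` assigns GT order with
a warning). Overlapping reference footprints are an error, not silently
resolved: phased panels are non-overlapping after allele selection, so
overlap signals a data bug.

The offset map is stored as collinear blocks (personal_start, ref_start,
length); gaps on the personal axis are insertion intervals, gaps on the
reference axis are deletions. The public view is the breakpoint list
(personal position, cumulative offset) with sentinel (0, 0): an insertion of
L bases contributes −L, a deletion +L, and the offset at a position is the
sum over preceding variants. Both directions of mapping are O(log n)
bisections; a reference position inside a deletion has no personal image,
a personal position inside an insertion no reference image.

## Change classification

Per haplotype: (1) detect personal palindromes with the same parameters as
the reference set; (2) map each personal midpoint back — a midpoint inside
an insertion is coded `IN_INSERTION` and keyed by the insertion's reference
anchor plus an ordinal (stable across individuals sharing the insertion);
a mapped midpoint equal to a reference palindrome midpoint is intact:
`IDENTICAL` (byte-identical span), `SAME_LEN_CHANGED`, `SHORTER` or
`LONGER`; otherwise the near-palindrome rescue applies — `NEAR_TO_PERFECT`
if the reference is near at that point, else `NEW`; (3) each unclaimed
reference palindrome is tested at the personal image of its midpoint —
`PERFECT_TO_NEAR` if a near-palindrome survives there, else `LOST` (a
midpoint falling in a deleted segment is `LOST` without rescue, as no
personal coordinate exists to test). Midpoint matching is exact: an indel
inside one arm legitimately produces LOST + NEW under this rule.

`SAME_LEN_CHANGED` exists so that `IDENTICAL` can mean byte-identical and
therefore be testable; equal-length, sequence-altered palindromes would
otherwise be indistinguishable from truly unchanged ones.

Haplotype combination: an individual varies at a key if either haplotype is
non-IDENTICAL; the allele count is the number of such haplotypes; when the
two non-IDENTICAL codes differ, the more disruptive wins (LOST >
PERFECT_TO_NEAR > SHORTER > LONGER > SAME_LEN_CHANGED > NEAR_TO_PERFECT >
NEW > IN_INSERTION). A key present on only one haplotype counts as
IDENTICAL on the other.

## Catalog and summaries

The catalog is a sparse palindrome × individual matrix (default entry
IDENTICAL); rows are the union of reference palindrome keys and keys seen in
any individual, ordered genomically. Conservation bins count, per row, the
individuals with any non-IDENTICAL code, bucketed into half-open intervals
[1,2), [2,5), [5,25), [25,200), [200,2000), [2000,∞) — half-open because a
partition must be disjoint even though conventional bin labels overlap at
their endpoints. Population summaries average per-sample code fractions
(computed over the full row set, summing to 1 per sample) within each
super-population; per-sample averaging is used rather than allele pooling
and is labeled as such.

## Annotation and enrichment

Region overlap uses the ≥ 1 bp rule on half-open intervals (an abutting
interval does not overlap). Derived labels are computed by interval set
algebra: intron∖exon, upstream∩intron, upstream∩exon, upstream-only.
The enrichment null defines the expected probability as the palindromic
fraction of assessed non-N bases — the only null that is independent of
genome build quirks and of any particular variant list; the fold ratio is
observed/expected and the null definition is recorded in the output
metadata. The gain-of-palindrome scan substitutes a SNP's risk allele and
compares perfect palindromes covering the SNP position within a
±(core_len/2 + 60) bp window before and after, consulting the near state
for NEAR_TO_PERFECT / PERFECT_TO_NEAR calls.

## Synthetic data: what it emulates and what it does not

The generator plants palindromes in spacer made of "AACC" repeats. The
spacer alphabet {A, C} contains no complementary pair, which makes three
guarantees *provable* rather than probable: no palindrome core can form in
pure spacer; extension beyond a plant always exhausts the mismatch budget
and trims back to the planted span; a single substitution in mid-spacer can
never create even a near-palindrome (three of any core's four pairs remain
spacer-only). Plants are separated by at least twice the maximal span plus
two core lengths, so they cannot interact.

Plant arms are random; because a random arm can by chance seed an extra
palindromic center inside the planted span, arms are drawn by bounded,
seed-deterministic rejection sampling: an arm is re-drawn until the
detector, run on the local window, reports exactly the planted expectation.
Similarly, each cohort variant's local pre/post configuration is verified
with detector primitives at generation time. Expected change codes are
*analytic* — a fixed effect-class table (core-breaking SNP →
PERFECT_TO_NEAR, arm-mismatch-fixing SNP → SAME_LEN_CHANGED, fix on an
over-budget arm → LONGER, outermost-pair break → SHORTER, mid-core
insertion or whole-span deletion → LOST, far-field SNP → no change, 2-bp
MNP perfecting a 2-mismatch core → NEW, SNP perfecting a 1-mismatch core →
NEAR_TO_PERFECT, insertion carrying its own spacer-padded palindrome →
IN_INSERTION) — and the brute-force oracle re-validates them independently
in the tests. A single SNP can never produce a plain NEW call under the
near-rescue rule (it changes at most one core pair, so the reference is
always at least near when the personal window is perfect), which is why the
NEW effect class uses a 2-base MNP.

The generator emulates phased, non-overlapping small variants with
population-specific carrier rates on an isolated-plant genome. It does not
emulate realistic base composition, repeat structure, mutation-rate or
allele-frequency spectra, linkage, overlapping or nested palindromes in
flanks, or structural variants. Passing the truth-table tests therefore
demonstrates correctness of the detection/liftover/classification logic
under controlled conditions, not performance characteristics on real
genomes, where nested palindromes and midpoint-shifting indels are common
and the LOST+NEW convention materially affects totals.

## Problem sizes and numerical choices

Default study conditions in the tests: detector–oracle equivalence on 200
random sequences of 0.5–2 kb at GC 0.2/0.5/0.8; liftover round-trips on a
20-sample cohort over 50 variant sites; classification recovery on 110
planted events across 10 effect classes and 6 samples; the enrichment null
at 10,000 uniform SNPs judged within 3 binomial standard errors. These
sizes exercise every code path and keep the whole suite in seconds on one
CPU. Floats in tables are formatted at 6 significant digits and all
orderings are fixed, so reruns are byte-identical; all randomness flows
from explicit seeds through `numpy.random.SeedSequence`.

Known limitations: no structural variants, inversions or CNVs; no
gap-containing inverted repeats (palindromes only, gap zero); no
re-phasing of unphased genotypes; whole-chromosome sequences are held in
memory (no FASTA random access); genome-wide palindrome *totals* depend on
the nested-span counting convention (`--maximal-only` exposes both views,
and no specific published total is asserted).
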
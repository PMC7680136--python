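"""Synthetic genomes, cohorts and annotation tables with known ground truth.

Every fixture is built so that its expected analysis outcome is provable,
not merely probable:

* spacers between planted palindromes are "AACC" repeats — an alphabet of
  {A, C} contains no complementary pair at all, so no palindrome core can
  form inside a spacer and extension beyond a plant always runs out of
  mismatch budget and is trimmed back to the planted span;
* each plant's random arm is validated in context against the package's own
  detector (bounded, seed-deterministic rejection sampling): an arm whose
  interior happens to seed an extra palindromic center is re-drawn, so the
  detected set equals the plant manifest exactly;
* each cohort variant's expected change code comes from a fixed analytic
  effect-class table; the local pre/post windows are checked with detector
  primitives at generation time, and the analytic codes are independently
  re-validated by a brute-force oracle in the test suite.

Effect classes and their expected individual-level change codes:

    core_break        -> PERFECT_TO_NEAR   (SNP breaks one core pair)
    arm_fix           -> SAME_LEN_CHANGED  (SNP repairs an interior arm mismatch)
    arm_fix_longer    -> LONGER            (repair frees budget on an over-budget arm)
    arm_break_outer   -> SHORTER           (SNP breaks the outermost pair)
    center_insertion  -> LOST              (1 bp inserted between the arms)
    span_deletion     -> LOST              (the whole span deleted)
    far_field         -> IDENTICAL        (SNP in mid-spacer; provably inert)
    mnp_gain          -> NEW               (2 bp MNP perfects a 2-mismatch core)
    near_fix          -> NEAR_TO_PERFECT   (SNP perfects a 1-mismatch core)
    ins_palindrome    -> IN_INSERTION      (insertion carrying its own palindrome)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detect import (
    DetectionParams,
    extend_center,
    find_palindromes,
    is_near_palindrome_at,
)
from .diff import ChangeCode, make_insertion_key, make_key
from .seqio import GenomeSequence, reverse_complement

SPACER_MOTIF = "AACC"
_BASES = np.array(list("ACGT"))

EFFECT_CODES: dict[str, ChangeCode] = {
    "core_break": ChangeCode.PERFECT_TO_NEAR,
    "arm_fix": ChangeCode.SAME_LEN_CHANGED,
    "arm_fix_longer": ChangeCode.LONGER,
    "arm_break_outer": ChangeCode.SHORTER,
    "center_insertion": ChangeCode.LOST,
    "span_deletion": ChangeCode.LOST,
    "far_field": ChangeCode.IDENTICAL,
    "mnp_gain": ChangeCode.NEW,
    "near_fix": ChangeCode.NEAR_TO_PERFECT,
    "ins_palindrome": ChangeCode.IN_INSERTION,
}


class SynthError(ValueError):
    pass


def random_genome(length: int, gc: float = 0.5, seed: int = 0) -> GenomeSequence:
    """i.i.d. random genome with P(G) + P(C) = gc; deterministic per seed."""
    if length <= 0:
        raise SynthError("length must be > 0")
    if not 0 <= gc <= 1:
        raise SynthError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(_BASES, size=length, p=p)
    return GenomeSequence(name="synth", bases="".join(bases))


def spacer(length: int) -> str:
    reps = SPACER_MOTIF * (length // len(SPACER_MOTIF) + 1)
    return reps[:length]


def _mismatching_base(rng, partner: str) -> str:
    """A base that does not complement `partner` (and is not N)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[partner]
    choices = [b for b in "ACGT" if b != comp]
    return choices[rng.integers(len(choices))]


def _build_plant_seq(
    rng,
    arm_len: int,
    arm_mismatch_pairs: Sequence[int] = (),
    core_mismatch_pairs: Sequence[int] = (),
    core_len: int = 8,
) -> str:
    """One planted (near-)palindrome string of length 2*arm_len.

    Pair k (1-based from the midpoint) is (P[A-k], P[A+k-1]); listed pairs
    are corrupted on the right-hand side.
    """
    h = core_len // 2
    if arm_len < h:
        raise SynthError(f"arm_len must be >= {h}")
    for k in arm_mismatch_pairs:
        if not h < k <= arm_len:
            raise SynthError(f"arm mismatch pair {k} outside ({h}, {arm_len}]")
    for k in core_mismatch_pairs:
        if not 1 <= k <= h:
            raise SynthError(f"core mismatch pair {k} outside [1, {h}]")
    left = "".join(_BASES[rng.integers(4, size=arm_len)])
    right = list(reverse_complement(left))
    for k in list(arm_mismatch_pairs) + list(core_mismatch_pairs):
        partner = left[arm_len - k]
        right[k - 1] = _mismatching_base(rng, partner)
    return left + "".join(right)


@dataclass
class PlantSpec:
    """Requested plant geometry; effect decides mismatch layout defaults."""

    arm_len: int = 10
    arm_mismatch_pairs: tuple[int, ...] = ()
    core_mismatch_pairs: tuple[int, ...] = ()


@dataclass
class Plant:
    """A realized plant: local geometry plus its reference placement."""

    index: int
    start: int  # reference span start (0-based)
    arm_len: int
    arm_mismatch_pairs: tuple[int, ...]
    core_mismatch_pairs: tuple[int, ...]
    expected_span: tuple[int, int]  # detected span in the reference (perfect plants)
    is_perfect_plant: bool

    @property
    def center(self) -> int:
        return self.start + self.arm_len

    @property
    def end(self) -> int:
        return self.start + 2 * self.arm_len


def _expected_ref_span(plant_start: int, arm_len: int, mm_pairs: Sequence[int]) -> tuple[int, int]:
    """Detected span of a plant: full span unless >4 arm mismatches, in which
    case extension stops before the 5th and trims to the last matched pair."""
    c = plant_start + arm_len
    mm = sorted(mm_pairs)
    if len(mm) <= 4:
        return (plant_start, plant_start + 2 * arm_len)
    k = mm[4] - 1
    while k in mm:
        k -= 1
    return (c - k, c + k)


def plant_palindrome(
    seq: GenomeSequence,
    pos: int,
    arm_len: int,
    mismatch_positions: Sequence[int] = (),
    seed: int = 0,
    core_mismatch_pairs: Sequence[int] = (),
    params: DetectionParams = DetectionParams(),
    max_tries: int = 200,
) -> GenomeSequence:
    """Write a validated plant at [pos, pos + 2*arm_len).

    The surrounding bases should be spacer-like ({A,C} only) so flanking
    pairs cannot complement. The arm is re-drawn (deterministically from
    `seed`) until the detector, run on the local window, reports exactly the
    expected span and nothing else.
    """
    span = 2 * arm_len
    if pos < 0 or pos + span > len(seq):
        raise SynthError("plant does not fit in sequence")
    for attempt in range(max_tries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        plant = _build_plant_seq(
            rng, arm_len, mismatch_positions, core_mismatch_pairs, params.core_len
        )
        new_bases = seq.bases[:pos] + plant + seq.bases[pos + span :]
        out = GenomeSequence(name=seq.name, bases=new_bases)
        if _plant_is_clean(
            out, pos, arm_len, mismatch_positions, core_mismatch_pairs, params
        ):
            return out
    raise SynthError(f"could not realize a clean plant at {pos} in {max_tries} tries")


_WINDOW_MARGIN = 16  # extension past a plant reaches at most 4 pairs into spacer


def _local_window(seq: GenomeSequence, lo: int, hi: int) -> tuple[GenomeSequence, int]:
    ws = max(0, lo - _WINDOW_MARGIN)
    we = min(len(seq), hi + _WINDOW_MARGIN)
    return GenomeSequence(name=seq.name, bases=seq.bases[ws:we]), ws


def _plant_is_clean(
    seq: GenomeSequence,
    pos: int,
    arm_len: int,
    arm_mm: Sequence[int],
    core_mm: Sequence[int],
    params: DetectionParams,
) -> bool:
    """True iff local detection agrees exactly with the plant's expectation."""
    win, ws = _local_window(seq, pos, pos + 2 * arm_len)
    found = find_palindromes(win, params)
    if core_mm:
        # a near plant must be invisible to the perfect detector, and its
        # near state must match the planted core mismatch count
        if found:
            return False
        near = is_near_palindrome_at(win, pos + arm_len - ws, params)
        return near == (len(core_mm) <= 1)
    exp = _expected_ref_span(pos - ws, arm_len, arm_mm)
    return [(p.start, p.end) for p in found] == [exp]


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class VariantSpec:
    """A VCF record in normalized (stripped) coordinates plus raw alleles."""

    pos: int  # 1-based VCF POS of the raw record
    ref: str
    alt: str


@dataclass
class PlantedEffect:
    plant: Plant
    effect: str
    variant: Optional[VariantSpec]
    key: str  # catalog row key the effect acts on
    expected_code: ChangeCode
    carriers: dict[str, tuple[int, int]] = field(default_factory=dict)
    # sample -> (hap0 carries, hap1 carries) as 0/1


@dataclass
class CohortSim:
    """Everything a test needs: sequences, files' contents, and the truth."""

    reference: GenomeSequence
    effects: list[PlantedEffect]
    samples: list[str]
    populations: dict[str, str]
    vcf_text: str
    panel_text: str
    seed: int

    def expected_hap_code(self, eff: PlantedEffect, sample: str, hap: int) -> ChangeCode:
        if eff.carriers.get(sample, (0, 0))[hap]:
            return eff.expected_code
        return ChangeCode.IDENTICAL

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "samples": self.samples,
            "populations": self.populations,
            "effects": [
                {
                    "effect": e.effect,
                    "key": e.key,
                    "expected_code": e.expected_code.value,
                    "plant_span": [e.plant.start, e.plant.end],
                    "variant": None
                    if e.variant is None
                    else {"pos": e.variant.pos, "ref": e.variant.ref, "alt": e.variant.alt},
                    "carriers": {s: list(c) for s, c in e.carriers.items()},
                }
                for e in self.effects
            ],
        }


DEFAULT_EFFECT_MIX = (
    "core_break",
    "arm_fix",
    "arm_fix_longer",
    "arm_break_outer",
    "center_insertion",
    "span_deletion",
    "far_field",
    "mnp_gain",
    "near_fix",
    "ins_palindrome",
)


def _plant_spec_for_effect(effect: str) -> PlantSpec:
    if effect == "arm_fix":
        return PlantSpec(arm_len=10, arm_mismatch_pairs=(6, 8))
    if effect == "arm_fix_longer":
        return PlantSpec(arm_len=15, arm_mismatch_pairs=(5, 7, 9, 11, 13))
    if effect == "mnp_gain":
        return PlantSpec(arm_len=10, core_mismatch_pairs=(1, 2))
    if effect == "near_fix":
        return PlantSpec(arm_len=10, core_mismatch_pairs=(2,))
    return PlantSpec(arm_len=10)


def _comp(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[b]


def _apply_local(bases: str, vpos0: int, ref: str, alt: str) -> str:
    """Apply one raw variant (0-based position) to a string."""
    assert bases[vpos0 : vpos0 + len(ref)] == ref
    return bases[:vpos0] + alt + bases[vpos0 + len(ref) :]


def _effect_checks_out(
    genome: GenomeSequence,
    plant: Plant,
    effect: str,
    variant: VariantSpec,
    params: DetectionParams,
) -> bool:
    """Verify with detector primitives that the variant produces exactly the
    analytically expected local configuration (no side-effect palindromes)."""
    win, ws = _local_window(genome, plant.start, plant.end)
    vpos0 = variant.pos - 1 - ws
    post = GenomeSequence(
        name=win.name, bases=_apply_local(win.bases, vpos0, variant.ref, variant.alt)
    )
    c = plant.center - ws
    found = find_palindromes(post, params)
    spans = [(p.start, p.end) for p in found]
    delta = len(variant.alt) - len(variant.ref)

    if effect == "core_break":
        # no perfect palindrome survives locally; the reference stays near
        return spans == [] and is_near_palindrome_at(post, c, params)
    if effect == "arm_fix":
        s, e = plant.expected_span
        return spans == [(s - ws, e - ws)]
    if effect == "arm_fix_longer":
        return spans == [(plant.start - ws, plant.end - ws)]
    if effect == "arm_break_outer":
        return spans == [(plant.start + 1 - ws, plant.end - 1 - ws)]
    if effect == "center_insertion":
        # the inserted base misaligns the arms: nothing perfect remains and
        # the reference midpoint's personal image (shifted by the insertion)
        return spans == [] and not is_near_palindrome_at(post, c + delta, params)
    if effect == "span_deletion":
        return spans == []
    if effect in ("mnp_gain", "near_fix"):
        return spans == [(plant.start - ws, plant.end - ws)]
    raise SynthError(f"unknown effect {effect}")


def _make_variant(
    genome: GenomeSequence, plant: Plant, effect: str, rng, params: DetectionParams
) -> Optional[VariantSpec]:
    """Construct the effect's VCF record (raw, anchor-base style)."""
    bases = genome.bases
    A, s = plant.arm_len, plant.start
    c = plant.center

    def snp_at(i: int, new: str) -> VariantSpec:
        return VariantSpec(pos=i + 1, ref=bases[i], alt=new)

    if effect == "core_break":
        k = 2 + int(rng.integers(0, 2))  # interior core pair 2 or 3
        i = c + k - 1
        return snp_at(i, _mismatching_base(rng, bases[c - k]))
    if effect in ("arm_fix", "arm_fix_longer"):
        k = plant.arm_mismatch_pairs[0]
        i = c + k - 1
        return snp_at(i, _comp(bases[c - k]))
    if effect == "arm_break_outer":
        i = c + A - 1
        return snp_at(i, _mismatching_base(rng, bases[c - A]))
    if effect == "center_insertion":
        ins = "ACGT"[int(rng.integers(4))]
        return VariantSpec(pos=c, ref=bases[c - 1], alt=bases[c - 1] + ins)
    if effect == "span_deletion":
        return VariantSpec(pos=s, ref=bases[s - 1 : plant.end], alt=bases[s - 1])
    if effect == "mnp_gain":
        return VariantSpec(
            pos=c + 1,
            ref=bases[c : c + 2],
            alt=_comp(bases[c - 1]) + _comp(bases[c - 2]),
        )
    if effect == "near_fix":
        k = plant.core_mismatch_pairs[0]
        i = c + k - 1
        return snp_at(i, _comp(bases[c - k]))
    raise SynthError(f"unknown effect {effect}")


def simulate_cohort(
    n_events: int = 10,
    populations: dict[str, tuple[int, float]] | None = None,
    effect_mix: Sequence[str] = DEFAULT_EFFECT_MIX,
    seed: int = 0,
    params: DetectionParams = DetectionParams(),
    chrom: str = "chrS",
) -> CohortSim:
    """Build a planted genome, a phased cohort VCF and the truth manifest.

    n_events plants are laid out left to right, cycling through effect_mix;
    each gets one VCF record whose expected change code is fixed by its
    effect class. populations maps super-population label to
    (n_samples, per-haplotype carrier rate), default
    {"AFR": (3, 0.5), "EUR": (3, 0.25)}.
    """
    if populations is None:
        populations = {"AFR": (3, 0.5), "EUR": (3, 0.25)}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))

    max_span = 2 * max(_plant_spec_for_effect(e).arm_len for e in effect_mix)
    gap = 2 * max_span + 2 * params.core_len  # spec separation guarantee

    effects_todo = [effect_mix[i % len(effect_mix)] for i in range(n_events)]

    bases_parts: list[str] = [spacer(gap)]
    cursor = gap
    plants: list[Plant] = []
    pending: list[tuple[str, Plant]] = []
    genome_parts_positions: list[int] = []

    # first pass: lay out plants in spacer with per-plant validated arms
    for idx, effect in enumerate(effects_todo):
        spec = _plant_spec_for_effect(effect)
        span = 2 * spec.arm_len
        if effect in ("far_field", "ins_palindrome"):
            # these act in spacer; reserve a spacer stretch instead of a plant
            plant = Plant(
                index=idx,
                start=cursor,
                arm_len=spec.arm_len,
                arm_mismatch_pairs=(),
                core_mismatch_pairs=(),
                expected_span=(cursor, cursor),
                is_perfect_plant=False,
            )
            bases_parts.append(spacer(span))
        else:
            plant = Plant(
                index=idx,
                start=cursor,
                arm_len=spec.arm_len,
                arm_mismatch_pairs=spec.arm_mismatch_pairs,
                core_mismatch_pairs=spec.core_mismatch_pairs,
                expected_span=(0, 0),  # placed below
                is_perfect_plant=not spec.core_mismatch_pairs,
            )
            bases_parts.append("P" * span)  # placeholder, filled in second pass
            genome_parts_positions.append(cursor)
        pending.append((effect, plant))
        plants.append(plant)
        cursor += span
        bases_parts.append(spacer(gap))
        cursor += gap

    scaffold = "".join(bases_parts)
    genome = GenomeSequence(name=chrom, bases=scaffold.replace("P", "A"))

    # second pass: realize each plant (validated), then its variant (validated)
    effects: list[PlantedEffect] = []
    for idx, (effect, plant) in enumerate(pending):
        if effect == "far_field":
            i = plant.start + plant.arm_len  # mid-spacer
            alt = "G" if genome.bases[i] != "G" else "T"
            variant = VariantSpec(pos=i + 1, ref=genome.bases[i], alt=alt)
            effects.append(
                PlantedEffect(
                    plant=plant,
                    effect=effect,
                    variant=variant,
                    key=make_key(chrom, i),
                    expected_code=ChangeCode.IDENTICAL,
                )
            )
            continue
        if effect == "ins_palindrome":
            eff = _realize_ins_palindrome(genome, plant, idx, seed, params, chrom)
            effects.append(eff)
            continue

        for attempt in range(200):
            try:
                genome2 = plant_palindrome(
                    genome,
                    plant.start,
                    plant.arm_len,
                    plant.arm_mismatch_pairs,
                    seed=int(
                        np.random.SeedSequence([seed, idx + 1, attempt]).generate_state(1)[0]
                        % (2**31)
                    ),
                    core_mismatch_pairs=plant.core_mismatch_pairs,
                    params=params,
                    max_tries=1,
                )
            except SynthError:
                continue
            plant.expected_span = _expected_ref_span(
                plant.start, plant.arm_len, plant.arm_mismatch_pairs
            )
            vrng = np.random.default_rng(np.random.SeedSequence([seed, idx + 1, attempt, 7]))
            variant = _make_variant(genome2, plant, effect, vrng, params)
            if variant is not None and _effect_checks_out(
                genome2, plant, effect, variant, params
            ):
                genome = genome2
                break
        else:
            raise SynthError(f"could not realize effect {effect} at plant {idx}")

        if effect in ("mnp_gain", "near_fix"):
            key = make_key(chrom, plant.center)
        else:
            key = make_key(chrom, (plant.expected_span[0] + plant.expected_span[1]) // 2)
        effects.append(
            PlantedEffect(
                plant=plant,
                effect=effect,
                variant=variant,
                key=key,
                expected_code=EFFECT_CODES[effect],
            )
        )

    # assign carriers per sample haplotype
    samples: list[str] = []
    pops: dict[str, str] = {}
    for pop, (n, _rate) in sorted(populations.items()):
        for i in range(n):
            name = f"{pop}{i:03d}"
            samples.append(name)
            pops[name] = pop
    crng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    for eff in effects:
        if eff.variant is None:
            continue
        for sample in samples:
            rate = populations[pops[sample]][1]
            h0 = int(crng.random() < rate)
            h1 = int(crng.random() < rate)
            if h0 or h1:
                eff.carriers[sample] = (h0, h1)

    vcf_text = _write_vcf_text(chrom, len(genome), effects, samples)
    panel_text = "sample\tpop\tsuper_pop\tgender\n" + "".join(
        f"{s}\t{pops[s]}\t{pops[s]}\tNA\n" for s in samples
    )
    return CohortSim(
        reference=genome,
        effects=effects,
        samples=samples,
        populations=pops,
        vcf_text=vcf_text,
        panel_text=panel_text,
        seed=seed,
    )


def _realize_ins_palindrome(
    genome: GenomeSequence,
    plant: Plant,
    idx: int,
    seed: int,
    params: DetectionParams,
    chrom: str,
) -> PlantedEffect:
    """An insertion in mid-spacer carrying a spacer-padded perfect palindrome."""
    anchor = plant.start + plant.arm_len  # insertion before this ref base
    pad = spacer(params.core_len)
    arm = 6
    for attempt in range(200):
        rng = np.random.default_rng(np.random.SeedSequence([seed, idx + 1, attempt, 3]))
        pal = _build_plant_seq(rng, arm, core_len=params.core_len)
        inserted = pad + pal + pad
        # validate in the personal context: window around the insertion site
        win, ws = _local_window(genome, anchor - 4, anchor + 4)
        loc = anchor - ws
        post = GenomeSequence(
            name=chrom, bases=win.bases[:loc] + inserted + win.bases[loc:]
        )
        found = find_palindromes(post, params)
        exp_start = loc + len(pad)
        if [(p.start, p.end) for p in found] == [(exp_start, exp_start + 2 * arm)]:
            variant = VariantSpec(
                pos=anchor, ref=genome.bases[anchor - 1], alt=genome.bases[anchor - 1] + inserted
            )
            return PlantedEffect(
                plant=plant,
                effect="ins_palindrome",
                variant=variant,
                key=make_insertion_key(chrom, anchor, 0),
                expected_code=ChangeCode.IN_INSERTION,
            )
    raise SynthError("could not realize ins_palindrome")


def _write_vcf_text(
    chrom: str, ref_len: int, effects: Sequence[PlantedEffect], samples: Sequence[str]
) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={ref_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    recs = sorted(
        (e for e in effects if e.variant is not None), key=lambda e: e.variant.pos
    )
    for i, eff in enumerate(recs):
        v = eff.variant
        gts = []
        for s in samples:
            h0, h1 = eff.carriers.get(s, (0, 0))
            gts.append(f"{h0}|{h1}")
        lines.append(
            f"{chrom}\t{v.pos}\tv{i}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


def write_cohort(sim: CohortSim, out_dir) -> dict:
    """Write FASTA, VCF, panel and manifest; returns the path map."""
    from pathlib import Path

    from .seqio import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "reference.fa",
        "vcf": out / "cohort.vcf",
        "panel": out / "panel.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(paths["fasta"], [sim.reference])
    paths["vcf"].write_text(sim.vcf_text)
    paths["panel"].write_text(sim.panel_text)
    paths["manifest"].write_text(json.dumps(sim.manifest(), indent=1))
    return {k: str(v) for k, v in paths.items()}


def toy_gwas_snps(
    pals, ref_length: int, n_in: int, n_out: int, seed: int = 0
) -> list:
    """GWAS SNPs with a known number of in-palindrome hits, for enrichment
    arithmetic checks."""
    from .annotate import GwasSnp, merge_intervals

    rng = np.random.default_rng(seed)
    spans = merge_intervals([(p.start, p.end) for p in pals])
    inside = [i for s, e in spans for i in range(s, e)]
    covered = set(inside)
    outside = [i for i in range(ref_length) if i not in covered]
    if len(inside) < 1 and n_in:
        raise SynthError("no palindromic bases to place SNPs in")
    snps = []
    for j in range(n_in):
        pos0 = inside[int(rng.integers(len(inside)))]
        snps.append(GwasSnp(rsid=f"rs_in{j}", chrom=pals[0].chrom, pos=pos0 + 1, trait="toy"))
    for j in range(n_out):
        pos0 = outside[int(rng.integers(len(outside)))]
        snps.append(GwasSnp(rsid=f"rs_out{j}", chrom=pals[0].chrom, pos=pos0 + 1, trait="toy"))
    return snps


def uniform_snps(chrom: str, length: int, n: int, seed: int = 0) -> list:
    """n SNP positions placed uniformly at random (the enrichment null)."""
    from .annotate import GwasSnp

    rng = np.random.default_rng(seed)
    pos = rng.integers(0, length, size=n)
    return [
        GwasSnp(rsid=f"rsU{i}", chrom=chrom, pos=int(p) + 1, trait="null")
        for i, p in enumerate(pos)
    ]
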
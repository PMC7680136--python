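"""Sequence I/O and base-level complement semantics.

All coordinates in this package are 0-based, half-open. Conversion to the
1-based conventions of VCF/GWAS happens only at those format boundaries.
Soft-masked (lowercase) bases are uppercased and treated as ordinary bases;
IUPAC ambiguity codes other than N are collapsed to N (N never participates
in palindrome formation, so nothing is lost downstream).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# every IUPAC code that is not a concrete base collapses to N
_AMBIGUITY = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})


class SequenceError(ValueError):
    """Invalid sequence content or malformed record."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome/contig over the alphabet {A,C,G,T,N}."""

    name: str
    bases: str
    n_ambiguous: int = field(default=0, compare=False)

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    @classmethod
    def from_raw(cls, name: str, raw: str) -> "GenomeSequence":
        """Normalize arbitrary FASTA text: uppercase, collapse ambiguity to N."""
        up = raw.upper()
        norm = up.translate(_AMBIGUITY)
        bad = set(norm) - VALID_BASES
        if bad:
            raise SequenceError(
                f"record {name!r}: invalid characters {sorted(bad)!r}"
            )
        n_amb = sum(a != b for a, b in zip(up, norm))
        if n_amb:
            logger.info("record %s: %d ambiguity codes converted to N", name, n_amb)
        return cls(name=name, bases=norm, n_ambiguous=n_amb)


def _validate(seq: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)!r}")


def complement(seq: str) -> str:
    """Base-wise complement (A<->T, C<->G, N->N), order preserved."""
    _validate(seq)
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement; an involution on {A,C,G,T,N} strings."""
    _validate(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def is_complementary(a: str, b: str) -> bool:
    """True iff single bases a, b form a Watson-Crick pair. N never pairs."""
    if a == "N" or b == "N":
        return False
    return _COMPLEMENT[ord(a)] == ord(b)


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[GenomeSequence]:
    """Read a (possibly gzipped) FASTA file into GenomeSequence records.

    Record names are the header token up to the first whitespace, preserved
    verbatim ("chr3" and "3" dialects are not normalized here). An empty file
    yields an empty list; a record with an empty sequence is an error.
    """
    path = Path(path)
    out: list[GenomeSequence] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if len(rec.seq) == 0:
                raise SequenceError(f"record {rec.id!r} has zero-length sequence")
            out.append(GenomeSequence.from_raw(rec.id, str(rec.seq)))
    return out


def write_fasta(path, seqs: Iterable[GenomeSequence]) -> None:
    """Write records as FASTA wrapped at 60 columns (gzip if path ends .gz)."""
    path = Path(path)
    records = [
        SeqRecord(Seq(s.bases), id=s.name, description="") for s in seqs
    ]
    with _open_maybe_gzip(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def strip_chr(name: str) -> str:
    """Chromosome-name matching key: 'chr1' and '1' compare equal."""
    return name[3:] if name.lower().startswith("chr") else name
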
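"""Population-scale palindrome variation catalog.

The catalog is a palindrome x individual matrix: row i is a palindrome seen
in the reference or in any individual, column j is an individual, and the
entry is the individual-level change code (default IDENTICAL, stored
sparsely). From it we derive how conserved each palindrome is across the
cohort (how many individuals it varied in) and per-super-population change
profiles (AFR, AMR, EAS, EUR, SAS in the 1000 Genomes panel dialect).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .diff import ChangeCode, IndividualChange, parse_key

DEFAULT_CONSERVATION_EDGES = (1, 2, 5, 25, 200, 2000, math.inf)


class CatalogError(ValueError):
    pass


@dataclass
class CatalogMatrix:
    """Sparse palindrome x individual matrix of change codes."""

    rows: list[str]  # ordered palindrome keys
    columns: list[str]  # ordered sample ids
    entries: dict[tuple[str, str], ChangeCode] = field(default_factory=dict)
    populations: dict[str, str] = field(default_factory=dict)
    allele_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def code_at(self, key: str, sample: str) -> ChangeCode:
        return self.entries.get((key, sample), ChangeCode.IDENTICAL)

    def to_dense(self) -> pd.DataFrame:
        """Materialized dense matrix (small cohorts only)."""
        df = pd.DataFrame(
            ChangeCode.IDENTICAL.value, index=self.rows, columns=self.columns
        )
        for (key, sample), code in self.entries.items():
            df.loc[key, sample] = code.value
        return df


def read_panel(path) -> dict[str, str]:
    """1000 Genomes panel dialect: tab-separated with sample, pop, super_pop
    columns (header row); returns sample -> super-population."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "super_pop" not in cols:
        raise CatalogError("panel needs 'sample' and 'super_pop' columns")
    return dict(zip(df[cols["sample"]], df[cols["super_pop"]]))


def build_matrix(
    change_lists: Mapping[str, Sequence[IndividualChange]],
    panel: Mapping[str, str],
    ref_keys: Optional[Iterable[str]] = None,
) -> CatalogMatrix:
    """Assemble the catalog from per-sample individual-level change lists.

    Rows are the union of keys seen in any sample plus (optionally) all
    reference palindrome keys; only non-IDENTICAL codes are stored. A sample
    absent from the panel gets population "NA" with a warning.
    """
    import logging

    keys: set[str] = set(ref_keys) if ref_keys else set()
    for changes in change_lists.values():
        keys.update(c.key for c in changes)
    rows = sorted(keys, key=parse_key)
    columns = sorted(change_lists)
    entries: dict[tuple[str, str], ChangeCode] = {}
    allele_counts: dict[tuple[str, str], int] = {}
    for sample, changes in change_lists.items():
        for c in changes:
            if c.code != ChangeCode.IDENTICAL:
                entries[(c.key, sample)] = c.code
                allele_counts[(c.key, sample)] = c.allele_count
    populations = {}
    for sample in columns:
        if sample in panel:
            populations[sample] = panel[sample]
        else:
            logging.getLogger(__name__).warning("sample %s missing from panel", sample)
            populations[sample] = "NA"
    return CatalogMatrix(
        rows=rows,
        columns=columns,
        entries=entries,
        populations=populations,
        allele_counts=allele_counts,
    )


@dataclass(frozen=True)
class ConservationSummary:
    """Fractions of palindromes varying in a given number of individuals."""

    bins: tuple[tuple[str, float], ...]  # (interval label, fraction of rows)
    unchanged_fraction: float
    n_rows: int


def conservation_summary(
    m: CatalogMatrix, bin_edges: Sequence[float] = DEFAULT_CONSERVATION_EDGES
) -> ConservationSummary:
    """Bin each palindrome by the number of individuals it varied in.

    Bins are half-open [e_i, e_{i+1}) so they partition; rows varying in no
    individual make up unchanged_fraction. Fractions sum to 1.
    """
    if not m.rows:
        raise CatalogError("empty catalog matrix")
    counts_per_row = {key: 0 for key in m.rows}
    for (key, _sample), code in m.entries.items():
        if code != ChangeCode.IDENTICAL:
            counts_per_row[key] += 1
    edges = list(bin_edges)
    bin_counts = [0] * (len(edges) - 1)
    unchanged = 0
    for n in counts_per_row.values():
        if n == 0:
            unchanged += 1
            continue
        for i in range(len(bin_counts)):
            if edges[i] <= n < edges[i + 1]:
                bin_counts[i] += 1
                break
    total = len(m.rows)
    labels = [
        f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(bin_counts))
    ]
    return ConservationSummary(
        bins=tuple((lab, c / total) for lab, c in zip(labels, bin_counts)),
        unchanged_fraction=unchanged / total,
        n_rows=total,
    )


def sample_code_fractions(m: CatalogMatrix, sample: str) -> dict[str, float]:
    """Fraction of this sample's rows carrying each change code (IDENTICAL
    included); fractions sum to 1 over the sample's row set."""
    total = len(m.rows)
    if total == 0:
        raise CatalogError("empty catalog matrix")
    counts = {code.value: 0 for code in ChangeCode}
    n_nondefault = 0
    for (key, s), code in m.entries.items():
        if s == sample:
            counts[code.value] += 1
            n_nondefault += 1
    counts[ChangeCode.IDENTICAL.value] = total - n_nondefault
    return {k: v / total for k, v in counts.items()}


def population_summary(m: CatalogMatrix) -> dict[str, dict[str, float]]:
    """Per-population mean (over its samples) of per-sample code fractions.

    Populations with zero samples are omitted.
    """
    by_pop: dict[str, list[str]] = {}
    for sample in m.columns:
        by_pop.setdefault(m.populations.get(sample, "NA"), []).append(sample)
    out = {}
    for pop, samples in sorted(by_pop.items()):
        fracs = [sample_code_fractions(m, s) for s in samples]
        out[pop] = {
            code.value: sum(f[code.value] for f in fracs) / len(fracs)
            for code in ChangeCode
        }
    return out


def write_matrix(m: CatalogMatrix, triplets_path, sidecar_path) -> None:
    """Sparse triplets (key, sample, code) as TSV plus a JSON sidecar with
    row order, column order and the population panel."""
    with open(triplets_path, "w") as fh:
        fh.write("key\tsample\tcode\n")
        for key in m.rows:
            for sample in m.columns:
                code = m.entries.get((key, sample))
                if code is not None:
                    fh.write(f"{key}\t{sample}\t{code.value}\n")
    with open(sidecar_path, "w") as fh:
        json.dump(
            {"rows": m.rows, "columns": m.columns, "populations": m.populations},
            fh,
            indent=1,
        )


def read_matrix(triplets_path, sidecar_path) -> CatalogMatrix:
    with open(sidecar_path) as fh:
        side = json.load(fh)
    m = CatalogMatrix(
        rows=side["rows"], columns=side["columns"], populations=side["populations"]
    )
    df = pd.read_csv(triplets_path, sep="\t")
    for _, row in df.iterrows():
        m.entries[(row["key"], row["sample"])] = ChangeCode(row["code"])
    return m
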
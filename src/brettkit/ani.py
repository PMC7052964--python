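"""Average nucleotide identity and genome summary statistics.

ANI here is pairwise percent identity over the comparable columns of a
multiple sequence alignment (typically a concatenated codon alignment of
single-copy orthologs): a column counts for a pair only when both
sequences carry an unambiguous A/C/G/T, so gaps and Ns are excluded
pairwise rather than alignment-wide.  Pairs with no comparable column are
reported as missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeIndex, merge_intervals


@dataclass
class AniMatrix:
    """Symmetric percent-identity matrix with a 100 diagonal."""

    taxa: list[str]
    values: np.ndarray

    def to_dataframe(self, decimals: int | None = 1) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)
        return df.round(decimals) if decimals is not None else df

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class GeneDensityResult:
    total_bp: int
    genic_bp: int

    @property
    def genic_pct(self) -> float:
        return 100.0 * self.genic_bp / self.total_bp


def ani_matrix(msa: Mapping[str, str]) -> AniMatrix:
    """Pairwise ANI over an aligned FASTA given as ``{name: sequence}``.

    All sequences must be the same length; the alphabet is ACGTN- (case
    insensitive).  Identity for a pair is ``100 * matches /
    comparable_sites`` over columns where both have an unambiguous base.
    """
    taxa = list(msa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    arrays = []
    for name in taxa:
        arr = np.frombuffer(msa[name].upper().encode(), dtype="S1")
        bad = ~np.isin(arr, np.frombuffer(b"ACGTN-", dtype="S1"))
        if bad.any():
            raise ValueError(f"{name}: unexpected character {arr[bad][0].decode()!r}")
        arrays.append(arr)
    unambiguous = [np.isin(a, np.frombuffer(b"ACGT", dtype="S1")) for a in arrays]
    n = len(taxa)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            comparable = unambiguous[i] & unambiguous[j]
            total = int(comparable.sum())
            if total == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            matches = int((arrays[i][comparable] == arrays[j][comparable]).sum())
            values[i, j] = values[j, i] = 100.0 * matches / total
    return AniMatrix(taxa, values)


def genic_fraction(
    gene_intervals: Iterable[tuple[str, int, int]],
    index: GenomeIndex,
) -> GeneDensityResult:
    """Percent of the assembly covered by the union of gene intervals."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in gene_intervals:
        length = index.length_of(contig)  # KeyError for unknown contigs
        if start < 0 or end > length or end < start:
            raise ValueError(f"interval [{start}, {end}) out of bounds on {contig!r}")
        per_contig.setdefault(contig, []).append((start, end))
    genic = 0
    for contig, ivs in per_contig.items():
        genic += sum(e - s for s, e in merge_intervals(ivs))
    return GeneDensityResult(total_bp=index.total_bp, genic_bp=genic)


def multicopy_fraction(table, species: str) -> float:
    """Percent of a species' occupied orthogroups that hold >= 2 genes."""
    if species not in table.species:
        raise KeyError(f"unknown species {species!r}")
    col = table.counts[species]
    present = col[col >= 1]
    if present.empty:
        raise ValueError(f"species {species!r} has no occupied orthogroup")
    return 100.0 * float((present >= 2).sum()) / float(len(present))
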
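"""Shared domain types and coordinate conventions.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
Conversions from 1-based inclusive file dialects (show-coords, VCF) happen
only in :mod:`brettkit.io`; no other module performs base conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned segment between a reference and a query interval.

    Intervals are 0-based half-open with ``start < end`` on both genomes;
    a reverse-orientation record still stores an ascending query interval,
    the strand being carried by :attr:`orientation`.  ``aligned_length``
    may differ from either span because of indels, but is at least 1.
    """

    ref_contig: str
    ref_start: int
    ref_end: int
    qry_contig: str
    qry_start: int
    qry_end: int
    orientation: str
    aligned_length: int
    identity_pct: float

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start < 1:
            raise ValueError(f"empty reference interval {self.ref_start}..{self.ref_end}")
        if self.qry_end - self.qry_start < 1:
            raise ValueError(f"empty query interval {self.qry_start}..{self.qry_end}")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct outside [0, 100]: {self.identity_pct}")


@dataclass
class GenomeIndex:
    """Ordered contig table: ``(contig_id, length in bp)`` pairs.

    Order is significant (it drives window generation and output order) and
    can be overridden from a one-column contig-order file.
    """

    entries: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, length in self.entries:
            if name in seen:
                raise ValueError(f"duplicate contig id {name!r}")
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
            seen.add(name)

    @property
    def contigs(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.entries)

    def __contains__(self, contig: str) -> bool:
        return any(name == contig for name, _ in self.entries)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries)

    def length_of(self, contig: str) -> int:
        for name, length in self.entries:
            if name == contig:
                return length
        raise KeyError(f"unknown contig {contig!r}")

    def reordered(self, order: Iterable[str]) -> "GenomeIndex":
        """Return a copy with contigs in the given order (all must exist)."""
        lengths = self.lengths
        out = []
        for name in order:
            if name not in lengths:
                raise KeyError(f"contig {name!r} not in index")
            out.append((name, lengths[name]))
        return GenomeIndex(out)


@dataclass
class SnpTrack:
    """Sorted SNP positions (0-based) on one contig."""

    contig_id: str
    positions: list[int]

    def __post_init__(self) -> None:
        for a, b in zip(self.positions, self.positions[1:]):
            if b <= a:
                raise ValueError(
                    f"positions on {self.contig_id} not strictly increasing at {a},{b}"
                )
        if self.positions and self.positions[0] < 0:
            raise ValueError("negative SNP position")

    @property
    def n_snps(self) -> int:
        return len(self.positions)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlapping or adjacent runs are merged."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for start, end in ivs:
        if end < start:
            raise ValueError(f"inverted interval [{start}, {end})")
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def overlap_len(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))
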
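"""Window-based synteny-block detection from whole-genome alignments.

The algorithm slides fixed windows (default 20 kb, 10 kb step) over both
genomes, pairs reference and query windows through the alignments, merges
chains of concordant pairs into blocks, and trims reference-side overlaps
between discordant blocks.  Block counts rise with the number of structural
rearrangements separating the two genomes, which is what makes the count a
useful genome-wide rearrangement summary.

Definitions used here, since "concordant" admits several readings:

* Two window pairs are **concordant** iff they share the reference contig,
  the query contig and the orientation; their reference windows and their
  query windows each overlap or fall within ``max_gap_windows`` steps of
  one another; and the query offset progresses as the orientation implies:
  in the same direction as the reference for forward pairs (opposite for
  reverse), with the two pairs' support-weighted diagonals agreeing to a
  tolerance (default one step).  The diagonal constraint is what stops a
  chain from walking across a rearrangement junction that happens to be
  window-adjacent on both genomes.
* A **block** is the interval union of a connected component of the
  concordance relation.
* **Trimming** resolves reference-interval overlaps between blocks from
  different components: the block with less aligned support loses the
  overlap (ties go against the block later in reference order).  Query-side
  overlaps are deliberately left alone — the output is reference-anchored.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .core import FORWARD, REVERSE, AlignmentRecord, GenomeIndex, overlap_len


@dataclass(frozen=True)
class SyntenyConfig:
    """Tunable parameters of the window algorithm.

    window_size/step_size are the genome-window geometry in bp;
    min_support_bp is the minimum aligned bases linking a window pair for
    it to be kept; max_gap_windows is how many missing steps adjacency may
    bridge during merging.
    """

    window_size: int = 20_000
    step_size: int = 10_000
    min_support_bp: int = 2_000
    max_gap_windows: int = 1
    diag_tolerance_bp: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.step_size <= self.window_size:
            raise ValueError("need 0 < step_size <= window_size")
        if self.min_support_bp > self.window_size:
            raise ValueError("min_support_bp cannot exceed window_size")
        if self.max_gap_windows < 0:
            raise ValueError("max_gap_windows must be >= 0")
        if self.diag_tolerance_bp is not None and self.diag_tolerance_bp < 0:
            raise ValueError("diag_tolerance_bp must be >= 0")

    @property
    def diag_tol(self) -> int:
        """Maximum diagonal drift between concordant pairs (default: one step)."""
        if self.diag_tolerance_bp is not None:
            return self.diag_tolerance_bp
        return self.step_size


@dataclass(frozen=True)
class Window:
    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("empty window")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowPair:
    """A reference window linked to a query window by aligned bases.

    ``ref_anchor``/``qry_anchor`` are the support-weighted mean positions
    of the aligned bases inside the two windows; their difference (sum,
    for reverse pairs) estimates the collinear diagonal the pair sits on,
    which the merge step uses to keep chains from crossing rearrangement
    junctions.
    """

    ref_window: Window
    qry_window: Window
    orientation: str
    support_bp: int
    ref_anchor: float = 0.0
    qry_anchor: float = 0.0
    ref_sup: tuple[float, float] = (0.0, 0.0)
    qry_sup: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.support_bp < 1:
            raise ValueError("support_bp must be >= 1")

    @property
    def diagonal(self) -> float:
        """Invariant coordinate of the pair's collinear diagonal."""
        if self.orientation == FORWARD:
            return self.qry_anchor - self.ref_anchor
        return self.qry_anchor + self.ref_anchor


@dataclass
class SyntenyBlock:
    ref_contig: str
    ref_start: int
    ref_end: int
    qry_contig: str
    qry_start: int
    qry_end: int
    orientation: str
    n_windows: int
    support_bp: int
    # member pairs are carried for provenance/idempotence, not identity
    pairs: list[WindowPair] = field(default_factory=list, compare=False, repr=False)

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start


def window_genome(index: GenomeIndex, cfg: SyntenyConfig = SyntenyConfig()) -> list[Window]:
    """Tile each contig with sliding windows.

    Starts run 0, step, 2*step, ... while start < contig length; each
    window ends at ``min(start + window_size, length)``.  A final truncated
    window shorter than the step is merged into its predecessor (kept alone
    if it is the contig's only window), so no window shorter than the step
    exists unless the whole contig is that short.
    """
    out: list[Window] = []
    for contig, length in index:
        wins: list[Window] = []
        start = 0
        while start < length:
            end = min(start + cfg.window_size, length)
            wins.append(Window(contig, start, end))
            start += cfg.step_size
        if len(wins) >= 2 and wins[-1].length < cfg.step_size:
            last = wins.pop()
            prev = wins[-1]
            wins[-1] = Window(contig, prev.start, max(prev.end, last.end))
        out.extend(wins)
    return out


def _windows_by_contig(windows: Iterable[Window]) -> dict[str, tuple[list[int], list[Window]]]:
    per: dict[str, list[Window]] = {}
    for w in windows:
        per.setdefault(w.contig_id, []).append(w)
    out = {}
    for contig, wins in per.items():
        wins.sort(key=lambda w: (w.start, w.end))
        out[contig] = ([w.start for w in wins], wins)
    return out


def _overlapping(bundle, start: float, end: float, window_size: int) -> list[Window]:
    """Windows of one contig intersecting [start, end)."""
    starts, wins = bundle
    lo = bisect_left(starts, start - window_size)
    hi = bisect_right(starts, end)
    return [w for w in wins[lo:hi] if w.start < end and w.end > start]


def pair_windows(
    alignments: Sequence[AlignmentRecord],
    ref_windows: Sequence[Window],
    qry_windows: Sequence[Window],
    cfg: SyntenyConfig = SyntenyConfig(),
) -> list[WindowPair]:
    """Pair reference and query windows through the alignments.

    Each alignment's overlap with a reference window is projected linearly
    onto the alignment's query interval (mirrored for reverse orientation)
    and attributed to the query windows it intersects; support for a
    (ref window, qry window, orientation) triple is the summed projected
    overlap in query bp.  Triples below ``min_support_bp`` are dropped.
    """
    ref_by = _windows_by_contig(ref_windows)
    qry_by = _windows_by_contig(qry_windows)
    # per triple: [support_bp, bp-weighted qry midpoint sum, same for ref]
    acc: dict[tuple[Window, Window, str], list[float]] = {}
    for aln in alignments:
        if aln.ref_contig not in ref_by:
            raise ValueError(f"alignment references unknown reference contig {aln.ref_contig!r}")
        if aln.qry_contig not in qry_by:
            raise ValueError(f"alignment references unknown query contig {aln.qry_contig!r}")
        scale = (aln.qry_end - aln.qry_start) / (aln.ref_end - aln.ref_start)
        for rw in _overlapping(ref_by[aln.ref_contig], aln.ref_start, aln.ref_end, cfg.window_size):
            ov_start = max(rw.start, aln.ref_start)
            ov_end = min(rw.end, aln.ref_end)
            if aln.orientation == FORWARD:
                q0 = aln.qry_start + (ov_start - aln.ref_start) * scale
                q1 = aln.qry_start + (ov_end - aln.ref_start) * scale
            else:
                q0 = aln.qry_end - (ov_end - aln.ref_start) * scale
                q1 = aln.qry_end - (ov_start - aln.ref_start) * scale
            for qw in _overlapping(qry_by[aln.qry_contig], q0, q1, cfg.window_size):
                c0, c1 = max(q0, float(qw.start)), min(q1, float(qw.end))
                bp = c1 - c0
                if bp <= 0:
                    continue
                q_mid = (c0 + c1) / 2.0
                # ref positions aligned to the clipped query stretch
                if aln.orientation == FORWARD:
                    r_mid = aln.ref_start + (q_mid - aln.qry_start) / scale
                    r_lo = aln.ref_start + (c0 - aln.qry_start) / scale
                    r_hi = aln.ref_start + (c1 - aln.qry_start) / scale
                else:
                    r_mid = aln.ref_start + (aln.qry_end - q_mid) / scale
                    r_lo = aln.ref_start + (aln.qry_end - c1) / scale
                    r_hi = aln.ref_start + (aln.qry_end - c0) / scale
                entry = acc.setdefault(
                    (rw, qw, aln.orientation),
                    [0.0, 0.0, 0.0, float("inf"), float("-inf"), float("inf"), float("-inf")],
                )
                entry[0] += bp
                entry[1] += bp * q_mid
                entry[2] += bp * r_mid
                entry[3] = min(entry[3], r_lo)
                entry[4] = max(entry[4], r_hi)
                entry[5] = min(entry[5], c0)
                entry[6] = max(entry[6], c1)
    pairs = [
        WindowPair(rw, qw, orient, int(round(bp)),
                   ref_anchor=r_sum / bp, qry_anchor=q_sum / bp,
                   ref_sup=(r_lo, r_hi), qry_sup=(q_lo, q_hi))
        for (rw, qw, orient), (bp, q_sum, r_sum, r_lo, r_hi, q_lo, q_hi) in acc.items()
        if bp >= cfg.min_support_bp
    ]
    pairs.sort(key=lambda p: (p.ref_window.contig_id, p.ref_window.start,
                              p.qry_window.contig_id, p.qry_window.start, p.orientation))
    return pairs


def _close(a_start: int, a_end: int, b_start: int, b_end: int, tol: int) -> bool:
    return a_start <= b_end + tol and b_start <= a_end + tol


def concordant(p: WindowPair, q: WindowPair, cfg: SyntenyConfig) -> bool:
    """Whether two window pairs belong to the same collinear chain.

    Adjacency is measured on the aligned support intervals, not the window
    footprints: a 20 kb window can poke far past its segment's breakpoint,
    and footprint adjacency would let chains leak across junctions.
    """
    if p.orientation != q.orientation:
        return False
    if p.ref_window.contig_id != q.ref_window.contig_id:
        return False
    if p.qry_window.contig_id != q.qry_window.contig_id:
        return False
    tol = cfg.max_gap_windows * cfg.step_size
    if not _close(p.ref_sup[0], p.ref_sup[1], q.ref_sup[0], q.ref_sup[1], tol):
        return False
    if not _close(p.qry_sup[0], p.qry_sup[1], q.qry_sup[0], q.qry_sup[1], tol):
        return False
    if abs(p.diagonal - q.diagonal) > cfg.diag_tol:
        return False
    dr = q.ref_anchor - p.ref_anchor
    dq = q.qry_anchor - p.qry_anchor
    if p.orientation == FORWARD:
        return dr * dq >= 0
    return dr * dq <= 0


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _merge(pairs: Sequence[WindowPair], cfg: SyntenyConfig) -> list[SyntenyBlock]:
    """Merge connected components of the concordance relation into blocks."""
    order = sorted(range(len(pairs)),
                   key=lambda i: (pairs[i].ref_window.contig_id, pairs[i].ref_window.start))
    uf = _UnionFind(len(pairs))
    reach = cfg.window_size + cfg.max_gap_windows * cfg.step_size
    for a_pos, i in enumerate(order):
        pi = pairs[i]
        for j in order[a_pos + 1:]:
            pj = pairs[j]
            if pj.ref_window.contig_id != pi.ref_window.contig_id:
                break
            if pj.ref_window.start - pi.ref_window.end > reach:
                break  # no later pair can be ref-adjacent to pi
            if concordant(pi, pj, cfg):
                uf.union(i, j)
    groups: dict[int, list[WindowPair]] = {}
    for i, p in enumerate(pairs):
        groups.setdefault(uf.find(i), []).append(p)
    blocks = []
    for members in groups.values():
        blocks.append(
            SyntenyBlock(
                ref_contig=members[0].ref_window.contig_id,
                ref_start=min(p.ref_window.start for p in members),
                ref_end=max(p.ref_window.end for p in members),
                qry_contig=members[0].qry_window.contig_id,
                qry_start=min(p.qry_window.start for p in members),
                qry_end=max(p.qry_window.end for p in members),
                orientation=members[0].orientation,
                n_windows=len({p.ref_window for p in members}),
                support_bp=sum(p.support_bp for p in members),
                pairs=sorted(members, key=lambda p: (p.ref_window.start,
                                                     p.qry_window.start)),
            )
        )
    blocks.sort(key=_block_key)
    return blocks


def _block_key(b: SyntenyBlock):
    return (b.ref_contig, b.ref_start, b.ref_end, b.qry_contig, b.qry_start, b.orientation)


def trim_blocks(blocks: Iterable[SyntenyBlock]) -> list[SyntenyBlock]:
    """Resolve reference-interval overlaps between blocks.

    The block with smaller support is trimmed back to the winner's
    boundary; on equal support the block later in reference order loses.
    When the winner sits strictly inside the loser, the loser keeps its
    lower-coordinate part.  Blocks trimmed to nothing are dropped.
    Query intervals are left untouched.
    """
    blocks = sorted((replace(b) for b in blocks), key=_block_key)
    while True:
        # resolve the first overlap in reference-sorted order, then rescan:
        # a canonical processing order makes the fixpoint well defined
        clash = None
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                a, b = blocks[i], blocks[j]
                if a.ref_contig != b.ref_contig or b.ref_start >= a.ref_end:
                    break
                clash = (a, b)
                break
            if clash:
                break
        if clash is None:
            return blocks
        a, b = clash
        if b.support_bp > a.support_bp:
            winner, loser = b, a
        else:
            winner, loser = a, b  # ties: later block (b) loses
        if loser.ref_start < winner.ref_start:
            # keeps the lower-coordinate part even when the winner sits
            # strictly inside the loser
            loser.ref_end = winner.ref_start
        else:
            loser.ref_start = winner.ref_end
        blocks = sorted((x for x in blocks if x.ref_end - x.ref_start >= 1),
                        key=_block_key)


def merge_and_trim(pairs: Sequence[WindowPair], cfg: SyntenyConfig = SyntenyConfig()) -> list[SyntenyBlock]:
    """Merge concordant window pairs into blocks, then trim discordant overlaps."""
    return trim_blocks(_merge(pairs, cfg))


def count_blocks(blocks: Sequence[SyntenyBlock]) -> tuple[int, dict[str, int]]:
    """Total block count plus a per-reference-contig breakdown."""
    per = Counter(b.ref_contig for b in blocks)
    return len(blocks), dict(per)


def find_blocks(
    alignments: Sequence[AlignmentRecord],
    ref_index: GenomeIndex,
    qry_index: GenomeIndex,
    cfg: SyntenyConfig = SyntenyConfig(),
) -> list[SyntenyBlock]:
    """One-shot pipeline: window both genomes, pair, merge and trim."""
    ref_windows = window_genome(ref_index, cfg)
    qry_windows = window_genome(qry_index, cfg)
    pairs = pair_windows(alignments, ref_windows, qry_windows, cfg)
    return merge_and_trim(pairs, cfg)
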
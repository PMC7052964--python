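"""Synthetic genome inputs with known ground truth.

Every generator here is a pure function of its seed and parameters and
emits the same text formats the analysis stages read, so the whole
pipeline is exercisable without external data: rearranged genome pairs
with an exact segment map (standing in for a whole-genome aligner),
two-regime SNP mosaics mimicking loss-of-heterozygosity tracts, BLAST
best-hit tables with a planted horizontally-transferred fraction,
orthogroup count tables with planted family expansions, and codon-spaced
alignments at a requested pairwise identity.

Sequences are i.i.d. uniform over ACGT; no substitution or indel process
is modelled, because alignments are supplied from the truth map rather
than recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FORWARD, REVERSE, AlignmentRecord, GenomeIndex, SnpTrack
from .io import ALIEN_LINEAGE, SELF_LINEAGE

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_MAX_PLACEMENT_TRIES = 1000


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Segment:
    """One collinear piece of the truth map between reference and query."""

    ref_contig: str
    ref_start: int
    ref_end: int
    qry_contig: str
    qry_start: int
    qry_end: int
    orientation: str


@dataclass
class RearrangementTruth:
    """Exact record of the sampled events and the resulting segment map.

    ``segment_map`` tiles both genomes without overlap; a segment carries
    reverse orientation iff it was inverted an odd number of times.
    """

    events: list[dict]
    segment_map: list[Segment]
    ref_index: GenomeIndex = field(default_factory=GenomeIndex)
    qry_index: GenomeIndex = field(default_factory=GenomeIndex)


@dataclass
class _Piece:
    ref_contig: str
    ref_start: int
    ref_end: int
    strand: int  # +1 forward, -1 inverted

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    def split(self, offset: int) -> tuple["_Piece", "_Piece"]:
        """Split at a query offset into this piece (0 < offset < length)."""
        if not 0 < offset < self.length:
            raise ValueError("split offset outside piece")
        if self.strand > 0:
            cut = self.ref_start + offset
            return (_Piece(self.ref_contig, self.ref_start, cut, 1),
                    _Piece(self.ref_contig, cut, self.ref_end, 1))
        cut = self.ref_end - offset
        return (_Piece(self.ref_contig, cut, self.ref_end, -1),
                _Piece(self.ref_contig, self.ref_start, cut, -1))


def _boundaries(pieces: list[_Piece]) -> list[int]:
    out = [0]
    for p in pieces:
        out.append(out[-1] + p.length)
    return out


def _split_contig(pieces: list[_Piece], pos: int) -> int:
    """Ensure a piece boundary at query offset ``pos``; return its piece index."""
    off = 0
    for i, p in enumerate(pieces):
        if pos == off:
            return i
        if off < pos < off + p.length:
            left, right = p.split(pos - off)
            pieces[i:i + 1] = [left, right]
            return i + 1
        off += p.length
    if pos == off:
        return len(pieces)
    raise ValueError(f"position {pos} outside contig of length {off}")


def _valid_cut(pos: int, boundaries: list[int], min_segment: int) -> bool:
    return all(abs(pos - b) >= min_segment for b in boundaries)


def sample_rearrangement_truth(
    seed: int,
    contig_lengths: Sequence[int],
    n_translocations: int,
    n_inversions: int,
    min_segment: int = 20_000,
) -> RearrangementTruth:
    """Sample rearrangement events and build the exact segment map.

    Events are applied sequentially (translocations first, then
    inversions); every new breakpoint must land at least ``min_segment``
    bp from every existing breakpoint of its contig, with bounded
    rejection retries, which keeps all truth segments window-resolvable
    and makes event lists nested across increasing event counts for a
    fixed seed.
    """
    if any(l < 4 * min_segment for l in contig_lengths):
        raise ValueError("every contig must be at least 4 * min_segment long")
    if n_translocations < 0 or n_inversions < 0:
        raise ValueError("event counts must be >= 0")
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    ref_names = [f"ref_{i + 1}" for i in range(len(contig_lengths))]
    qry_names = [f"qry_{i + 1}" for i in range(len(contig_lengths))]
    contigs: dict[str, list[_Piece]] = {
        q: [_Piece(r, 0, length, 1)]
        for q, r, length in zip(qry_names, ref_names, contig_lengths)
    }
    lengths = {q: l for q, l in zip(qry_names, contig_lengths)}
    weights = np.array([lengths[q] for q in qry_names], dtype=float)
    weights /= weights.sum()
    events: list[dict] = []

    def draw_interval(contig: str) -> tuple[int, int] | None:
        bounds = _boundaries(contigs[contig])
        length = lengths[contig]
        for _ in range(_MAX_PLACEMENT_TRIES):
            a, b = sorted(int(x) for x in rng.integers(0, length + 1, size=2))
            if b - a < min_segment:
                continue
            if _valid_cut(a, bounds, min_segment) and _valid_cut(b, bounds, min_segment):
                return a, b
        return None

    for _ in range(n_translocations):
        src = qry_names[int(rng.choice(len(qry_names), p=weights))]
        iv = draw_interval(src)
        if iv is None:
            raise RuntimeError("could not place translocation without violating min_segment")
        a, b = iv
        dst = qry_names[int(rng.choice(len(qry_names), p=weights))]
        ins = None
        dst_bounds = _boundaries(contigs[dst])
        for _ in range(_MAX_PLACEMENT_TRIES):
            c = int(rng.integers(0, lengths[dst] + 1))
            if dst == src and a <= c <= b:
                continue
            near = dst_bounds + ([a, b] if dst == src else [])
            if _valid_cut(c, near, min_segment):
                ins = c
                break
        if ins is None:
            raise RuntimeError("could not place translocation destination")
        i0 = _split_contig(contigs[src], a)
        i1 = _split_contig(contigs[src], b)
        moved = contigs[src][i0:i1]
        del contigs[src][i0:i1]
        lengths[src] -= b - a
        if dst == src and ins > b:
            ins -= b - a
        j = _split_contig(contigs[dst], ins)
        contigs[dst][j:j] = moved
        lengths[dst] += b - a
        events.append({"kind": "translocation", "src": src, "start": a, "end": b,
                       "dst": dst, "insert_at": ins})

    for _ in range(n_inversions):
        contig = qry_names[int(rng.choice(len(qry_names), p=weights))]
        iv = draw_interval(contig)
        if iv is None:
            raise RuntimeError("could not place inversion without violating min_segment")
        a, b = iv
        i0 = _split_contig(contigs[contig], a)
        i1 = _split_contig(contigs[contig], b)
        flipped = [
            _Piece(p.ref_contig, p.ref_start, p.ref_end, -p.strand)
            for p in reversed(contigs[contig][i0:i1])
        ]
        contigs[contig][i0:i1] = flipped
        events.append({"kind": "inversion", "contig": contig, "start": a, "end": b})

    segment_map: list[Segment] = []
    for q in qry_names:
        off = 0
        for p in contigs[q]:
            segment_map.append(
                Segment(p.ref_contig, p.ref_start, p.ref_end,
                        q, off, off + p.length,
                        FORWARD if p.strand > 0 else REVERSE)
            )
            off += p.length
    ref_index = GenomeIndex(list(zip(ref_names, contig_lengths)))
    qry_index = GenomeIndex([(q, lengths[q]) for q in qry_names])
    return RearrangementTruth(events, segment_map, ref_index, qry_index)


def make_rearranged_pair(
    seed: int,
    contig_lengths: Sequence[int],
    n_translocations: int,
    n_inversions: int,
    min_segment: int = 20_000,
) -> tuple[dict[str, str], dict[str, str], RearrangementTruth]:
    """Generate a genome pair differing by known translocations/inversions.

    Returns ``(ref_seqs, qry_seqs, truth)``; the query genome is the
    reference with the sampled events applied, so each truth segment's
    query substring equals its reference substring (reverse-complemented
    when inverted).
    """
    truth = sample_rearrangement_truth(seed, contig_lengths, n_translocations,
                                       n_inversions, min_segment)
    rng = np.random.default_rng([int(seed) % (2**31), 12])
    ref_seqs = {
        name: rng.choice(_BASES, size=length).tobytes().decode()
        for name, length in truth.ref_index
    }
    qry_seqs: dict[str, str] = {name: "" for name, _ in truth.qry_index}
    for seg in truth.segment_map:
        piece = ref_seqs[seg.ref_contig][seg.ref_start:seg.ref_end]
        if seg.orientation == REVERSE:
            piece = _revcomp(piece)
        qry_seqs[seg.qry_contig] += piece
    return ref_seqs, qry_seqs, truth


def truth_to_alignments(truth: RearrangementTruth) -> list[AlignmentRecord]:
    """Transcribe the truth segment map into perfect alignment records."""
    return [
        AlignmentRecord(
            ref_contig=s.ref_contig, ref_start=s.ref_start, ref_end=s.ref_end,
            qry_contig=s.qry_contig, qry_start=s.qry_start, qry_end=s.qry_end,
            orientation=s.orientation,
            aligned_length=s.ref_end - s.ref_start,
            identity_pct=100.0,
        )
        for s in truth.segment_map
    ]


def simulate_snp_track(
    seed: int,
    index: GenomeIndex,
    region_plan: Sequence[tuple[str, int, int, float]],
    ) -> list[SnpTrack]:
    """Simulate a heterozygous/homozygous SNP-density mosaic.

    ``region_plan`` rows are ``(contig, start, end, density_snps_per_kb)``
    and must tile each contig of the index.  Per region the SNP count is
    Poisson(density * length / 1000) and positions are uniform without
    replacement.
    """
    by_contig: dict[str, list[tuple[int, int, float]]] = {}
    for contig, start, end, dens in region_plan:
        if contig not in index:
            raise KeyError(f"region on unknown contig {contig!r}")
        if dens < 0:
            raise ValueError("density must be >= 0")
        by_contig.setdefault(contig, []).append((start, end, dens))
    for contig, regions in by_contig.items():
        regions.sort()
        length = index.length_of(contig)
        cursor = 0
        for start, end, _ in regions:
            if start != cursor or end <= start:
                raise ValueError(f"regions do not tile contig {contig!r}")
            cursor = end
        if cursor != length:
            raise ValueError(f"regions do not tile contig {contig!r}")
    rng = np.random.default_rng([int(seed) % (2**31), 21])
    tracks = []
    for contig, _ in index:
        positions: list[int] = []
        for start, end, dens in by_contig.get(contig, []):
            size = end - start
            n = int(rng.poisson(dens * size / 1000.0))
            if n > size:
                raise ValueError(
                    f"expected SNP count {n} exceeds region size {size} on {contig!r}"
                )
            if n:
                positions.extend(
                    int(p) + start for p in rng.choice(size, size=n, replace=False)
                )
        tracks.append(SnpTrack(contig, sorted(positions)))
    return tracks


def make_blast_table(
    seed: int,
    n_proteins: int,
    hgt_fraction: float,
    e_native: tuple[float, float] = (-120.0, -40.0),
    e_alien: tuple[float, float] = (-4.0, 0.0),
    hits_per_lineage: int = 2,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, bool]]:
    """Generate a mixed fungal/bacterial best-hit table with planted HGT.

    ``e_native`` and ``e_alien`` are log10 E-value ranges for a protein's
    favoured and disfavoured lineage respectively; planted HGT proteins
    have the two swapped.  Returns the hit table (outfmt-6 columns plus
    lineage), the subject->lineage map, and per-protein truth labels
    (True = planted HGT).
    """
    if not 0.0 <= hgt_fraction <= 1.0:
        raise ValueError("hgt_fraction must be in [0, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 31])
    n_hgt = int(round(hgt_fraction * n_proteins))
    hgt_idx = set(rng.choice(n_proteins, size=n_hgt, replace=False).tolist()) if n_hgt else set()
    rows = []
    lineage_map: dict[str, str] = {}
    labels: dict[str, bool] = {}
    for i in range(n_proteins):
        pid = f"protein_{i + 1:05d}"
        is_hgt = i in hgt_idx
        labels[pid] = is_hgt
        for lineage in (SELF_LINEAGE, ALIEN_LINEAGE):
            favoured = (lineage == ALIEN_LINEAGE) == is_hgt
            lo, hi = e_native if favoured else e_alien
            for j in range(hits_per_lineage):
                subject = (f"fungus_{i + 1:05d}_{j}" if lineage == SELF_LINEAGE
                           else f"bacterium_{i + 1:05d}_{j}")
                log_e = float(rng.uniform(lo, hi))
                evalue = 10.0 ** log_e
                lineage_map[subject] = lineage
                rows.append((pid, subject, evalue, -10.0 * log_e))
    table = pd.DataFrame(rows, columns=["query_id", "subject_id", "evalue", "bitscore"])
    table["subject_lineage"] = table["subject_id"].map(lineage_map)
    return table, lineage_map, labels


def make_count_table(
    seed: int,
    n_species: int,
    n_groups: int,
    planted: Sequence[tuple[str, str, int]] = (),
    background: str = "ones",
    background_lambda: float = 1.0,
):
    """Orthogroup count table with planted expansions on a flat background.

    ``planted`` rows are ``(group, species, count)`` and overwrite the
    background exactly.  Background is all-ones by default, or
    ``background='poisson'`` for 1 + Poisson(background_lambda) counts.
    """
    from .expansion import OrthogroupCountTable

    rng = np.random.default_rng([int(seed) % (2**31), 41])
    species = [f"sp{i + 1}" for i in range(n_species)]
    groups = [f"OG{i + 1:07d}" for i in range(n_groups)]
    if background == "ones":
        data = np.ones((n_groups, n_species), dtype=int)
    elif background == "poisson":
        data = 1 + rng.poisson(background_lambda, size=(n_groups, n_species))
    else:
        raise ValueError(f"unknown background {background!r}")
    df = pd.DataFrame(data, index=groups, columns=species)
    for group, sp, count in planted:
        if count < 0:
            raise ValueError("planted counts must be >= 0")
        df.loc[group, sp] = count
    return OrthogroupCountTable(df)


def _identity_to_leaf_rate(target_identity: float) -> float:
    # star topology: leaf pair identity (1-m)^2 + m^2/3 = t, solved for m
    t = target_identity
    disc = 1.0 - (4.0 / 3.0) * (1.0 - t)
    if disc < 0:
        raise ValueError("target identity below the 0.25 random-sequence floor")
    return 0.75 * (1.0 - math.sqrt(disc))


def make_codon_msa(
    seed: int,
    n_seqs: int,
    n_codons: int,
    target_identity: float,
    gap_rate: float = 0.0,
) -> dict[str, str]:
    """Codon-spaced alignment whose pairwise identities hit a target.

    Sequences are independent leaves of a star tree around a random
    ancestor; the per-leaf substitution rate is chosen so the expected
    identity of every leaf pair equals ``target_identity`` (valid down to
    the 0.25 floor of unrelated sequences).  ``gap_rate`` optionally
    converts bases to gaps, which downstream identity computations skip.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng([int(seed) % (2**31), 51])
    n_sites = 3 * n_codons
    m = _identity_to_leaf_rate(target_identity)
    ancestor = rng.integers(0, 4, size=n_sites)
    seqs: dict[str, str] = {}
    for i in range(n_seqs):
        leaf = ancestor.copy()
        mutate = rng.random(n_sites) < m
        # substitute with one of the three other bases, uniformly
        leaf[mutate] = (leaf[mutate] + rng.integers(1, 4, size=int(mutate.sum()))) % 4
        chars = _BASES[leaf]
        if gap_rate > 0:
            gaps = rng.random(n_sites) < gap_rate
            chars = chars.copy()
            chars[gaps] = b"-"
        seqs[f"tax{i + 1}"] = chars.tobytes().decode()
    return seqs
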
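"""SNP-density windows and loss-of-heterozygosity classification.

A diploid genome region that has undergone loss of heterozygosity (LOH)
shows near-zero heterozygous SNP density, while the rest of the genome
sits orders of magnitude higher; any threshold between the two regimes
separates them.  The default calls a contig homozygous when its mean
density falls below 0.5 SNPs/kb, and the genome summary reports the
aggregate density of each class (total SNPs over total bp, not the mean
of per-contig densities) plus the bp fraction of the genome in the
homozygous class.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

from .core import GenomeIndex, SnpTrack
from .synteny import SyntenyConfig, window_genome

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


@dataclass
class DensityWindow:
    contig: str
    start: int
    end: int
    n_snps: int

    @property
    def density(self) -> float:
        """SNPs per kb."""
        return 1000.0 * self.n_snps / (self.end - self.start)


@dataclass
class LohCall:
    contig: str
    length_bp: int
    n_snps: int
    mean_density: float
    state: str


@dataclass
class LohSummary:
    """Aggregate per-class densities and the homozygous bp share."""

    homozygous_bp: int
    heterozygous_bp: int
    homozygous_snps: int
    heterozygous_snps: int

    @property
    def homozygous_density(self) -> float | None:
        if self.homozygous_bp == 0:
            return None
        return 1000.0 * self.homozygous_snps / self.homozygous_bp

    @property
    def heterozygous_density(self) -> float | None:
        if self.heterozygous_bp == 0:
            return None
        return 1000.0 * self.heterozygous_snps / self.heterozygous_bp

    @property
    def homozygous_fraction_pct(self) -> float:
        total = self.homozygous_bp + self.heterozygous_bp
        return 100.0 * self.homozygous_bp / total if total else 0.0


def snp_density(
    track: SnpTrack,
    index: GenomeIndex,
    window: int = 10_000,
    step: int = 10_000,
) -> list[DensityWindow]:
    """Windowed SNP density over one contig (half-open membership)."""
    length = index.length_of(track.contig_id)
    if track.positions and track.positions[-1] >= length:
        raise ValueError(
            f"SNP at {track.contig_id}:{track.positions[-1]} beyond contig length {length}"
        )
    cfg = SyntenyConfig(window_size=window, step_size=step,
                        min_support_bp=min(2000, window))
    sub_index = GenomeIndex([(track.contig_id, length)])
    out = []
    for w in window_genome(sub_index, cfg):
        n = bisect_left(track.positions, w.end) - bisect_left(track.positions, w.start)
        out.append(DensityWindow(w.contig_id, w.start, w.end, n))
    return out


def classify_loh(
    tracks: Sequence[SnpTrack],
    index: GenomeIndex,
    threshold: float = 0.5,
    level: str = "contig",
    window: int = 10_000,
    step: int = 10_000,
) -> tuple[list[LohCall], LohSummary]:
    """Classify contigs (or windows) as homozygous vs heterozygous.

    A unit is homozygous iff its mean SNP density is strictly below
    ``threshold`` SNPs/kb.  Contigs of the index without a track count as
    zero-SNP (homozygous) contigs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if level not in ("contig", "window"):
        raise ValueError("level must be 'contig' or 'window'")
    by_contig = {t.contig_id: t for t in tracks}
    for t in tracks:
        if t.contig_id not in index:
            raise KeyError(f"track contig {t.contig_id!r} missing from index")
    calls: list[LohCall] = []
    for contig, length in index:
        track = by_contig.get(contig, SnpTrack(contig, []))
        if level == "contig":
            units = [DensityWindow(contig, 0, length, track.n_snps)]
        else:
            units = snp_density(track, index, window, step)
        for u in units:
            dens = u.density
            state = HOMOZYGOUS if dens < threshold else HETEROZYGOUS
            calls.append(LohCall(contig if level == "contig" else f"{contig}:{u.start}-{u.end}",
                                 u.end - u.start, u.n_snps, dens, state))
    hom = [c for c in calls if c.state == HOMOZYGOUS]
    het = [c for c in calls if c.state == HETEROZYGOUS]
    summary = LohSummary(
        homozygous_bp=sum(c.length_bp for c in hom),
        heterozygous_bp=sum(c.length_bp for c in het),
        homozygous_snps=sum(c.n_snps for c in hom),
        heterozygous_snps=sum(c.n_snps for c in het),
    )
    return calls, summary
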
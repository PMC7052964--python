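"""Readers and writers for every external format the pipeline touches.

Everything entering the package is normalized here to 0-based half-open
coordinates with an explicit orientation flag; everything leaving is
converted back to the target dialect's convention.  Supported formats:

* MUMmer ``show-coords -T`` tabular alignments (1-based inclusive, reverse
  strand encoded as a descending query interval) and PAF (already 0-based).
* FASTA (plain or aligned) via Biopython.
* VCF 4.x SNP calls via cyvcf2 (reading) and a plain-text writer.
* OrthoFinder ``Orthogroups.GeneCount.tsv``-style count tables.
* BLAST outfmt-6 tables plus a two-column subject->lineage map.
* Gene->GO two-column TSV, BED intervals, contig-order lists.
* Synteny block TSV (BED-like) and Circos link files.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FORWARD, REVERSE, AlignmentRecord, GenomeIndex, SnpTrack

SELF_LINEAGE = "self_lineage"
ALIEN_LINEAGE = "alien_lineage"

# ---------------------------------------------------------------------------
# genome indexes / FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{contig_id: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def index_from_fasta(path: str | Path) -> GenomeIndex:
    return GenomeIndex([(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")])


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Read a 2+ column TSV (``contig<TAB>length``, .fai-style) into a GenomeIndex."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            try:
                entries.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad contig length {fields[1]!r}") from exc
    return GenomeIndex(entries)


def write_genome_index(index: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in index:
            fh.write(f"{name}\t{length}\n")


def read_contig_order(path: str | Path) -> list[str]:
    """One contig id per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# ---------------------------------------------------------------------------
# alignment coordinates


def _parse_show_coords_row(fields: list[str], lineno: int, path: str) -> AlignmentRecord:
    # show-coords -T: S1 E1 S2 E2 LEN1 LEN2 %IDY [...] REF QRY
    try:
        s1, e1, s2, e2 = (int(fields[i]) for i in range(4))
        len1, len2 = int(fields[4]), int(fields[5])
        idy = float(fields[6])
        ref_contig, qry_contig = fields[-2], fields[-1]
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:{lineno}: malformed show-coords row") from exc
    if s1 > e1:
        raise ValueError(f"{path}:{lineno}: descending reference interval unsupported")
    # 1-based inclusive -> 0-based half-open; reverse strand is given with
    # a descending query interval.
    ref_start, ref_end = s1 - 1, e1
    if s2 <= e2:
        qry_start, qry_end, orientation = s2 - 1, e2, FORWARD
    else:
        qry_start, qry_end, orientation = e2 - 1, s2, REVERSE
    return AlignmentRecord(
        ref_contig=ref_contig,
        ref_start=ref_start,
        ref_end=ref_end,
        qry_contig=qry_contig,
        qry_start=qry_start,
        qry_end=qry_end,
        orientation=orientation,
        aligned_length=max(len1, len2, 1),
        identity_pct=idy,
    )


def _parse_paf_row(fields: list[str], lineno: int, path: str) -> AlignmentRecord:
    # PAF: qname qlen qstart qend strand tname tlen tstart tend nmatch alnlen mapq
    try:
        qname = fields[0]
        qstart, qend = int(fields[2]), int(fields[3])
        strand = fields[4]
        tname = fields[5]
        tstart, tend = int(fields[7]), int(fields[8])
        nmatch, alnlen = int(fields[9]), int(fields[10])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:{lineno}: malformed PAF row") from exc
    identity = 100.0 * nmatch / alnlen if alnlen else 0.0
    return AlignmentRecord(
        ref_contig=tname,
        ref_start=tstart,
        ref_end=tend,
        qry_contig=qname,
        qry_start=qstart,
        qry_end=qend,
        orientation=FORWARD if strand == "+" else REVERSE,
        aligned_length=max(alnlen, 1),
        identity_pct=min(identity, 100.0),
    )


def read_coords(
    path: str | Path,
    dialect: str = "show_coords_tab",
    ref_index: GenomeIndex | None = None,
    qry_index: GenomeIndex | None = None,
) -> list[AlignmentRecord]:
    """Read pairwise whole-genome alignment coordinates.

    ``show_coords_tab`` is the ``show-coords -T`` dialect (header lines are
    skipped; data rows start with an integer).  ``paf`` is minimap2's PAF.
    If genome indexes are supplied, records naming unknown contigs raise.
    """
    if dialect not in ("show_coords_tab", "paf"):
        raise ValueError(f"unknown coords dialect {dialect!r}")
    records: list[AlignmentRecord] = []
    path = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if dialect == "show_coords_tab":
                # header block: program line, file paths, "[S1] [E1] ..." etc.
                try:
                    int(fields[0])
                except ValueError:
                    if records:
                        raise ValueError(f"{path}:{lineno}: malformed show-coords row")
                    continue
                rec = _parse_show_coords_row(fields, lineno, path)
            else:
                rec = _parse_paf_row(fields, lineno, path)
            if ref_index is not None and rec.ref_contig not in ref_index:
                raise ValueError(f"{path}:{lineno}: unknown reference contig {rec.ref_contig!r}")
            if qry_index is not None and rec.qry_contig not in qry_index:
                raise ValueError(f"{path}:{lineno}: unknown query contig {rec.qry_contig!r}")
            records.append(rec)
    return records


def write_coords(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    """Write alignments in the ``show-coords -T`` dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[TAGS]\n")
        for r in records:
            if r.orientation == FORWARD:
                s2, e2 = r.qry_start + 1, r.qry_end
            else:
                s2, e2 = r.qry_end, r.qry_start + 1
            fh.write(
                f"{r.ref_start + 1}\t{r.ref_end}\t{s2}\t{e2}\t"
                f"{r.ref_end - r.ref_start}\t{r.qry_end - r.qry_start}\t"
                f"{r.identity_pct:.2f}\t{r.ref_contig}\t{r.qry_contig}\n"
            )


# ---------------------------------------------------------------------------
# orthogroup gene counts


def read_genecounts(path: str | Path):
    """Read an OrthoFinder ``Orthogroups.GeneCount.tsv``-style table.

    First column is the orthogroup id, remaining columns are per-species
    integer counts; a trailing ``Total`` column, if present, is dropped.
    """
    from .expansion import OrthogroupCountTable  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an orthogroup column plus at least one species")
    group_col = df.columns[0]
    if df[group_col].duplicated().any():
        dup = df[group_col][df[group_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate orthogroup id {dup!r}")
    df = df.set_index(group_col)
    if df.columns[-1] == "Total":
        df = df.iloc[:, :-1]
    counts = pd.DataFrame(index=df.index)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="raise")
        if not (numeric == numeric.round()).all():
            raise ValueError(f"{path}: non-integer count in column {col!r}")
        counts[col] = numeric.astype(int)
    return OrthogroupCountTable(counts)


def write_genecounts(table, path: str | Path, total_column: bool = True) -> None:
    df = table.counts.copy()
    if total_column:
        df["Total"] = df.sum(axis=1)
    df.index.name = "Orthogroup"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF SNPs


def read_vcf_snps(path: str | Path, pass_filters: set[str] = frozenset({"PASS"})) -> list[SnpTrack]:
    """Read SNP positions from a VCF 4.x file, one track per contig seen.

    Only biallelic-style SNP rows (REF and every ALT of length 1) whose
    FILTER is in ``pass_filters`` are kept; positions become 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    per_contig: dict[str, list[int]] = {}
    for var in vcf:
        if len(var.REF) != 1:
            continue
        if not var.ALT or any(len(a) != 1 for a in var.ALT):
            continue
        filt = var.FILTER if var.FILTER is not None else "PASS"
        if filt not in pass_filters:
            continue
        per_contig.setdefault(var.CHROM, []).append(var.POS - 1)
    vcf.close()
    return [SnpTrack(contig, sorted(set(pos))) for contig, pos in per_contig.items()]


def write_vcf_snps(
    tracks: Sequence[SnpTrack],
    index: GenomeIndex,
    path: str | Path,
    ref_base: str = "A",
    alt_base: str = "C",
) -> None:
    """Write SNP tracks as a minimal VCF 4.2 file (positions back to 1-based)."""
    by_contig = {t.contig_id: t for t in tracks}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in index:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for name, length in index:
            track = by_contig.get(name)
            if track is None:
                continue
            for pos in track.positions:
                if pos >= length:
                    raise ValueError(f"SNP at {name}:{pos} beyond contig length {length}")
                fh.write(f"{name}\t{pos + 1}\t.\t{ref_base}\t{alt_base}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# BLAST tables and lineage maps


def read_lineage_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``subject_id<TAB>lineage`` with lineage self/alien."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or fields[1] not in (SELF_LINEAGE, ALIEN_LINEAGE):
                raise ValueError(
                    f"{path}:{lineno}: expected 'subject<TAB>{SELF_LINEAGE}|{ALIEN_LINEAGE}'"
                )
            out[fields[0]] = fields[1]
    return out


def read_blast_table(
    path: str | Path,
    lineage_map: dict[str, str],
    on_unmapped: str = "error",
) -> pd.DataFrame:
    """Read a BLAST outfmt-6 TSV and attach per-row lineage labels.

    Returns a DataFrame with columns ``query_id, subject_id, evalue,
    bitscore, subject_lineage``.  Subjects missing from the lineage map are
    an error by default (``on_unmapped='drop'`` drops those rows instead,
    which can bias the downstream Alien Index and is off by default).
    """
    if on_unmapped not in ("error", "drop"):
        raise ValueError("on_unmapped must be 'error' or 'drop'")
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 10, 11],
        names=["query_id", "subject_id", "evalue", "bitscore"],
    )
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative E-value")
    lineages = df["subject_id"].map(lineage_map)
    if lineages.isna().any():
        if on_unmapped == "error":
            missing = df.loc[lineages.isna(), "subject_id"].iloc[0]
            raise ValueError(f"{path}: subject {missing!r} missing from lineage map")
        df = df[lineages.notna()].reset_index(drop=True)
        lineages = lineages.dropna().reset_index(drop=True)
    df["subject_lineage"] = lineages
    return df


def write_blast_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write hits as BLAST outfmt-6 (12 columns; unused ones zero-filled)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.query_id}\t{row.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{row.evalue:.3g}\t{row.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# gene->GO annotations and BED intervals


def read_gene2go(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV ``gene<TAB>GO_term`` (one association per row)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                out.append((fields[0], int(fields[1]), int(fields[2])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED row") from exc
    return out


# ---------------------------------------------------------------------------
# synteny blocks

_BLOCK_HEADER = [
    "ref_contig", "ref_start", "ref_end", "qry_contig", "qry_start", "qry_end",
    "orientation", "n_windows", "support_bp",
]


def write_blocks(blocks, bed_path: str | Path, links_path: str | Path | None = None) -> None:
    """Write synteny blocks as a BED-like TSV and optionally a Circos link file.

    The BED-like file carries the query interval, orientation, window count
    and support in extra columns and round-trips through
    :func:`read_blocks` losslessly.  The Circos file has one ``ref qry``
    link per block.
    """
    with open(bed_path, "w") as fh:
        fh.write("#" + "\t".join(_BLOCK_HEADER) + "\n")
        for b in blocks:
            fh.write(
                f"{b.ref_contig}\t{b.ref_start}\t{b.ref_end}\t"
                f"{b.qry_contig}\t{b.qry_start}\t{b.qry_end}\t"
                f"{b.orientation}\t{b.n_windows}\t{b.support_bp}\n"
            )
    if links_path is not None:
        with open(links_path, "w") as fh:
            for b in blocks:
                fh.write(
                    f"{b.ref_contig} {b.ref_start} {b.ref_end} "
                    f"{b.qry_contig} {b.qry_start} {b.qry_end}\n"
                )


def read_blocks(bed_path: str | Path):
    """Read a block TSV written by :func:`write_blocks`."""
    from .synteny import SyntenyBlock

    out = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                out.append(
                    SyntenyBlock(
                        ref_contig=f[0], ref_start=int(f[1]), ref_end=int(f[2]),
                        qry_contig=f[3], qry_start=int(f[4]), qry_end=int(f[5]),
                        orientation=f[6], n_windows=int(f[7]), support_bp=int(f[8]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{bed_path}:{lineno}: malformed block row") from exc
    return out
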
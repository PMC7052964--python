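"""Full-run orchestration: a validated config, stage dispatch, and a manifest.

The config is a plain YAML mapping with one section per stage; unknown
keys are rejected so a typo cannot silently fall back to a default.
Orchestration adds no computation of its own — each stage is exactly the
corresponding module call — and identical config plus inputs produce
byte-identical outputs.  A ``manifest.json`` records the package version,
the resolved parameters, SHA-256 checksums of every input, and which
stages completed, so a run can be audited after the fact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from . import __version__
from . import ani as ani_mod
from . import expansion, hgt, io, loh
from .synteny import SyntenyConfig, count_blocks, find_blocks

_STAGE_KEYS: dict[str, set[str]] = {
    "synteny": {"ref_index", "qry_index", "coords", "dialect", "window_size",
                "step_size", "min_support_bp", "max_gap_windows"},
    "ani": {"msa", "decimals"},
    "stats": {"genes_bed", "index"},
    "expand": {"counts", "focal", "threshold", "averaging"},
    "enrich": {"study", "population", "gene2go", "alpha"},
    "hgt": {"blast", "lineage_map", "exclude", "threshold"},
    "loh": {"vcf", "index", "threshold", "level"},
}
_GLOBAL_KEYS = {"seed", "outdir", "stages"}


class StageError(RuntimeError):
    """A stage failed; carries the stage name for the abort message."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    raw: dict[str, Any]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw)

    def __post_init__(self) -> None:
        if not isinstance(self.raw, dict):
            raise ValueError("config must be a mapping")
        for key, value in self.raw.items():
            if key in _GLOBAL_KEYS:
                continue
            if key not in _STAGE_KEYS:
                raise ValueError(f"unknown config section {key!r}")
            unknown = set(value or {}) - _STAGE_KEYS[key]
            if unknown:
                raise ValueError(f"unknown key {sorted(unknown)[0]!r} in section {key!r}")

    @property
    def stages(self) -> list[str]:
        requested = self.raw.get("stages")
        if requested is None:
            requested = [k for k in _STAGE_KEYS if k in self.raw]
        for stage in requested:
            if stage not in _STAGE_KEYS:
                raise ValueError(f"unknown stage {stage!r}")
            if stage not in self.raw:
                raise ValueError(f"stage {stage!r} requested but not configured")
        return list(requested)

    def section(self, stage: str) -> dict[str, Any]:
        return dict(self.raw.get(stage) or {})


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _run_synteny(sec: dict, outdir: Path) -> dict:
    ref_index = io.read_genome_index(sec["ref_index"])
    qry_index = io.read_genome_index(sec["qry_index"])
    cfg = SyntenyConfig(
        window_size=int(sec.get("window_size", 20_000)),
        step_size=int(sec.get("step_size", 10_000)),
        min_support_bp=int(sec.get("min_support_bp", 2_000)),
        max_gap_windows=int(sec.get("max_gap_windows", 1)),
    )
    alignments = io.read_coords(sec["coords"], sec.get("dialect", "show_coords_tab"),
                                ref_index, qry_index)
    blocks = find_blocks(alignments, ref_index, qry_index, cfg)
    io.write_blocks(blocks, outdir / "synteny_blocks.tsv", outdir / "synteny_links.txt")
    total, per_contig = count_blocks(blocks)
    return {"n_blocks": total, "per_contig": per_contig,
            "outputs": ["synteny_blocks.tsv", "synteny_links.txt"]}


def _run_ani(sec: dict, outdir: Path) -> dict:
    msa = io.read_fasta(sec["msa"])
    matrix = ani_mod.ani_matrix(msa)
    df = matrix.to_dataframe(decimals=int(sec.get("decimals", 1)))
    df.to_csv(outdir / "ani_matrix.tsv", sep="\t")
    return {"taxa": matrix.taxa, "outputs": ["ani_matrix.tsv"]}


def _run_stats(sec: dict, outdir: Path) -> dict:
    index = io.read_genome_index(sec["index"])
    genes = io.read_bed_intervals(sec["genes_bed"])
    result = ani_mod.genic_fraction(genes, index)
    with open(outdir / "genome_stats.tsv", "w") as fh:
        fh.write("total_bp\tgenic_bp\tgenic_pct\n")
        fh.write(f"{result.total_bp}\t{result.genic_bp}\t{result.genic_pct:.2f}\n")
    return {"genic_pct": result.genic_pct, "outputs": ["genome_stats.tsv"]}


def _run_expand(sec: dict, outdir: Path) -> dict:
    table = io.read_genecounts(sec["counts"])
    focal = sec.get("focal") or table.species
    if isinstance(focal, str):
        focal = [s for s in focal.split(",") if s]
    averaging = sec.get("averaging")
    if isinstance(averaging, str):
        averaging = [s for s in averaging.split(",") if s]
    results = expansion.expansion_ratios(table, focal,
                                         threshold=float(sec.get("threshold", 2.0)),
                                         averaging_species=averaging)
    expansion.expansion_table(results).to_csv(outdir / "expansions.tsv", sep="\t", index=False)
    return {"n_flagged": sum(r.flagged for r in results), "outputs": ["expansions.tsv"]}


def _read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _run_enrich(sec: dict, outdir: Path) -> dict:
    results = expansion.go_enrichment(
        _read_gene_list(sec["study"]),
        _read_gene_list(sec["population"]),
        io.read_gene2go(sec["gene2go"]),
        alpha=float(sec.get("alpha", 0.05)),
    )
    expansion.enrichment_table(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return {"n_significant": sum(r.significant for r in results),
            "outputs": ["enrichment.tsv"]}


def _run_hgt(sec: dict, outdir: Path) -> dict:
    lineage_map = io.read_lineage_map(sec["lineage_map"])
    table = io.read_blast_table(sec["blast"], lineage_map)
    exclude = sec.get("exclude", [])
    if isinstance(exclude, str):
        exclude = [s for s in exclude.split(",") if s]
    results = hgt.screen(table, exclude_taxa=exclude,
                         threshold=float(sec.get("threshold", hgt.DEFAULT_THRESHOLD)))
    hgt.screen_table(results).to_csv(outdir / "alien_index.tsv", sep="\t", index=False)
    return {"n_candidates": sum(r.candidate for r in results),
            "outputs": ["alien_index.tsv"]}


def _run_loh(sec: dict, outdir: Path) -> dict:
    index = io.read_genome_index(sec["index"])
    tracks = io.read_vcf_snps(sec["vcf"])
    calls, summary = loh.classify_loh(tracks, index,
                                      threshold=float(sec.get("threshold", 0.5)),
                                      level=sec.get("level", "contig"))
    with open(outdir / "loh_calls.tsv", "w") as fh:
        fh.write("contig\tlength_bp\tn_snps\tdensity_snps_per_kb\tstate\n")
        for c in calls:
            fh.write(f"{c.contig}\t{c.length_bp}\t{c.n_snps}\t{c.mean_density:.4f}\t{c.state}\n")
    return {
        "homozygous_fraction_pct": summary.homozygous_fraction_pct,
        "homozygous_density": summary.homozygous_density,
        "heterozygous_density": summary.heterozygous_density,
        "outputs": ["loh_calls.tsv"],
    }


_RUNNERS: dict[str, Callable[[dict, Path], dict]] = {
    "synteny": _run_synteny, "ani": _run_ani, "stats": _run_stats,
    "expand": _run_expand, "enrich": _run_enrich, "hgt": _run_hgt, "loh": _run_loh,
}

_INPUT_KEYS = {"ref_index", "qry_index", "coords", "msa", "genes_bed", "index",
               "counts", "study", "population", "gene2go", "blast",
               "lineage_map", "vcf"}


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages in order; write outputs and a manifest.

    Any stage error aborts the run with the stage name; stages completed
    before the abort are still listed in the manifest, and the manifest's
    ``complete`` flag records whether every requested stage finished.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.raw,
        "inputs": {},
        "stages": {},
        "complete": False,
    }
    error: StageError | None = None
    for stage in config.stages:
        sec = config.section(stage)
        for key in _INPUT_KEYS & set(sec):
            path = sec[key]
            if not Path(path).exists():
                error = StageError(stage, FileNotFoundError(path))
                break
            manifest["inputs"][str(path)] = _sha256(path)
        if error:
            break
        try:
            manifest["stages"][stage] = _RUNNERS[stage](sec, outdir)
        except Exception as exc:  # abort, naming the stage
            error = StageError(stage, exc)
            break
    manifest["complete"] = error is None
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    if error:
        raise error
    return manifest
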
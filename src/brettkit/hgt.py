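"""Alien Index screening for horizontal gene transfer candidates.

For each protein the screen takes the best (smallest) BLAST E-value
against its own lineage (e.g. fungi) and against the alien lineage
(e.g. bacteria) and scores

    AI = ln(best_e_self + c) - ln(best_e_alien + c)

with pseudo-count ``c = 1e-200``; a lineage with no hit contributes
E = 1.  Large positive AI means the alien hit is far stronger than any
self-lineage hit, the signature expected of a horizontally acquired
gene; proteins with AI strictly greater than 20 are flagged as
candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import ALIEN_LINEAGE, SELF_LINEAGE

DEFAULT_PSEUDOCOUNT = 1e-200
DEFAULT_MISSING_E = 1.0
DEFAULT_THRESHOLD = 20.0


@dataclass
class AlienIndexResult:
    protein_id: str
    best_e_self: float | None
    best_e_alien: float | None
    ai: float
    candidate: bool


def best_hits(
    table: pd.DataFrame,
    exclude_taxa: Sequence[str] = (),
) -> dict[str, tuple[float | None, float | None]]:
    """Per-protein best self- and alien-lineage E-values.

    ``exclude_taxa`` substrings are matched against subject identifiers
    (used to drop hits to the query's own genus rather than resolving a
    taxonomy); proteins left with no rows at all are omitted.
    """
    df = table
    if exclude_taxa:
        mask = pd.Series(False, index=df.index)
        for taxon in exclude_taxa:
            mask |= df["subject_id"].str.contains(taxon, regex=False)
        df = df[~mask]
    out: dict[str, tuple[float | None, float | None]] = {}
    for pid, group in df.groupby("query_id", sort=True):
        if (group["evalue"] < 0).any():
            raise ValueError(f"negative E-value for {pid}")
        self_e = group.loc[group["subject_lineage"] == SELF_LINEAGE, "evalue"]
        alien_e = group.loc[group["subject_lineage"] == ALIEN_LINEAGE, "evalue"]
        out[pid] = (
            float(self_e.min()) if not self_e.empty else None,
            float(alien_e.min()) if not alien_e.empty else None,
        )
    return out


def alien_index(
    best_e_self: float | None,
    best_e_alien: float | None,
    c: float = DEFAULT_PSEUDOCOUNT,
    missing_e: float = DEFAULT_MISSING_E,
) -> float:
    """AI = ln(e_self + c) - ln(e_alien + c), missing E-values -> ``missing_e``."""
    e_self = missing_e if best_e_self is None else best_e_self
    e_alien = missing_e if best_e_alien is None else best_e_alien
    if e_self < 0 or e_alien < 0:
        raise ValueError("E-values must be >= 0")
    return math.log(e_self + c) - math.log(e_alien + c)


def screen(
    table: pd.DataFrame,
    exclude_taxa: Sequence[str] = (),
    threshold: float = DEFAULT_THRESHOLD,
    c: float = DEFAULT_PSEUDOCOUNT,
    missing_e: float = DEFAULT_MISSING_E,
) -> list[AlienIndexResult]:
    """Score every protein and flag candidates with AI strictly above threshold.

    Results are sorted by AI descending (ties by protein id).  The input
    table needs ``query_id``, ``subject_id``, ``evalue`` and
    ``subject_lineage`` columns (see :func:`brettkit.io.read_blast_table`).
    """
    results = [
        AlienIndexResult(pid, e_self, e_alien,
                         ai := alien_index(e_self, e_alien, c, missing_e),
                         ai > threshold)
        for pid, (e_self, e_alien) in best_hits(table, exclude_taxa).items()
    ]
    results.sort(key=lambda r: (-r.ai, r.protein_id))
    return results


def screen_table(results: Sequence[AlienIndexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_id, r.best_e_self, r.best_e_alien, r.ai, r.candidate) for r in results],
        columns=["protein_id", "best_e_self", "best_e_alien", "alien_index", "candidate"],
    )
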
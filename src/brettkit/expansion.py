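"""Gene-family expansion screen and hypergeometric GO enrichment.

The expansion statistic for a focal species in an orthogroup is the
gene count divided by the mean count over an averaging set of species
(all species in the table by default); families at ratio >= 2 are
flagged as expanded.  Flagged gene sets are then tested for GO-term
overrepresentation with an upper-tail hypergeometric test and Bonferroni
family-wise error-rate correction over the tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom


@dataclass
class OrthogroupCountTable:
    """Per-species gene counts per orthogroup (rows: groups, cols: species)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("counts must be >= 0")
        self.counts = self.counts.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class ExpansionResult:
    group: str
    species: str
    count: int
    mean_count: float
    ratio: float
    flagged: bool


@dataclass
class EnrichmentResult:
    term: str
    study_hits: int
    study_size: int
    population_hits: int
    population_size: int
    p_raw: float
    p_bonferroni: float
    significant: bool


def expansion_ratios(
    table: OrthogroupCountTable,
    focal_species: Sequence[str],
    threshold: float = 2.0,
    averaging_species: Sequence[str] | None = None,
) -> list[ExpansionResult]:
    """Count/mean-count ratios for focal species, flagged at ``threshold``.

    The mean is taken over ``averaging_species`` (default: every species
    in the table); orthogroups whose mean is 0 are skipped since the
    ratio is undefined there.
    """
    for sp in focal_species:
        if sp not in table.species:
            raise KeyError(f"unknown focal species {sp!r}")
    avg = list(averaging_species) if averaging_species is not None else table.species
    if not avg:
        raise ValueError("averaging set is empty")
    for sp in avg:
        if sp not in table.species:
            raise KeyError(f"unknown averaging species {sp!r}")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    means = table.counts[avg].mean(axis=1)
    out: list[ExpansionResult] = []
    for group in table.groups:
        mean = float(means.loc[group])
        if mean == 0.0:
            continue
        for sp in focal_species:
            count = int(table.counts.loc[group, sp])
            ratio = count / mean
            out.append(ExpansionResult(group, sp, count, mean, ratio, ratio >= threshold))
    return out


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` population size, ``K`` marked in the population, ``n`` drawn,
    ``k`` marked among the drawn.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def go_enrichment(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    gene2go: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric GO overrepresentation of a study set, Bonferroni-corrected.

    The sampling frame is the population; the term universe is every term
    with at least one population annotation, and only terms with at least
    one study hit are tested (the Bonferroni multiplier is the number of
    tested terms).  Term assignment is flat — no ontology-graph
    propagation to ancestor terms.
    """
    study = set(study_genes)
    population = set(population_genes)
    missing = study - population
    if missing:
        raise ValueError(f"study gene {sorted(missing)[0]!r} absent from population")
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for term in gene2go.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    tested = sorted(term_study)
    m = len(tested)
    results = []
    for term in tested:
        k, K = term_study[term], term_pop[term]
        p = hypergeom_tail(k, len(study), K, len(population))
        p_adj = min(1.0, p * m)
        results.append(
            EnrichmentResult(term, k, len(study), K, len(population),
                             p, p_adj, p_adj <= alpha)
        )
    results.sort(key=lambda r: (r.p_bonferroni, r.term))
    return results


def expansion_table(results: Sequence[ExpansionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.group, r.species, r.count, r.mean_count, r.ratio, r.flagged) for r in results],
        columns=["orthogroup", "species", "count", "mean_count", "ratio", "flagged"],
    )


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term, r.study_hits, r.study_size, r.population_hits, r.population_size,
          r.p_raw, r.p_bonferroni, r.significant) for r in results],
        columns=["term", "study_hits", "study_size", "population_hits",
                 "population_size", "p_raw", "p_bonferroni", "significant"],
    )
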
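"""Expansion ratios, hypergeometric tail, GO enrichment."""

import numpy as np
import pytest

from brettkit import expansion_ratios, go_enrichment, hypergeom_tail, make_count_table
from oracle import hypergeom_tail_enum


# ----------------------------------------------------------------- ratios

def test_ratio_flags_planted_expansion():
    table = make_count_table(1, 5, 10, planted=[("OG0000003", "sp1", 4)])
    results = {(r.group, r.species): r for r in expansion_ratios(table, ["sp1"])}
    hit = results[("OG0000003", "sp1")]
    assert hit.mean_count == pytest.approx(1.6)
    assert hit.ratio == pytest.approx(2.5)
    assert hit.flagged


def test_uniform_counts_are_never_flagged():
    table = make_count_table(1, 5, 8, planted=[
        (f"OG{i + 1:07d}", sp, 2) for i in range(8) for sp in
        ("sp1", "sp2", "sp3", "sp4", "sp5")])
    results = expansion_ratios(table, ["sp1", "sp2"])
    assert all(r.ratio == pytest.approx(1.0) and not r.flagged for r in results)


def test_single_species_retention_gives_high_ratio():
    table = make_count_table(1, 5, 3, planted=[
        ("OG0000002", "sp1", 2), ("OG0000002", "sp2", 0), ("OG0000002", "sp3", 0),
        ("OG0000002", "sp4", 0), ("OG0000002", "sp5", 0)])
    results = {(r.group, r.species): r for r in expansion_ratios(table, ["sp1"])}
    assert results[("OG0000002", "sp1")].ratio == pytest.approx(5.0)


def test_all_zero_group_is_skipped_and_order_invariance():
    table = make_count_table(1, 3, 2, planted=[
        ("OG0000001", sp, 0) for sp in ("sp1", "sp2", "sp3")])
    results = expansion_ratios(table, ["sp1"])
    assert [r.group for r in results] == ["OG0000002"]
    # permuting rows/columns leaves the per-cell results unchanged
    shuffled = type(table)(table.counts.iloc[::-1, ::-1])
    assert {(r.group, r.species, r.ratio) for r in expansion_ratios(shuffled, ["sp1"])} \
        == {(r.group, r.species, r.ratio) for r in results}


def test_averaging_subset_changes_the_mean():
    table = make_count_table(1, 4, 1, planted=[("OG0000001", "sp1", 4)])
    (over_all,) = expansion_ratios(table, ["sp1"])
    (over_two,) = expansion_ratios(table, ["sp1"], averaging_species=["sp1", "sp2"])
    assert over_all.mean_count == pytest.approx(7 / 4)
    assert over_two.mean_count == pytest.approx(2.5)


def test_empty_averaging_set_errors():
    table = make_count_table(1, 2, 1)
    with pytest.raises(ValueError, match="averaging"):
        expansion_ratios(table, ["sp1"], averaging_species=[])


def test_planted_expansions_are_recovered_exactly():
    # the row mean includes the expanded cell, so on a 5-species all-ones
    # background the smallest flaggable plant is 3 (ratio 3/1.4 ~ 2.14)
    for seed, count in [(0, 3), (1, 4), (2, 10)]:
        table = make_count_table(seed, 5, 50, planted=[("OG0000010", "sp2", count)])
        flagged = {(r.group, r.species)
                   for r in expansion_ratios(table, table.species) if r.flagged}
        assert flagged == {("OG0000010", "sp2")}


# ----------------------------------------------------- hypergeometric tail

def test_worked_example_three_of_three_draws():
    assert hypergeom_tail(3, 3, 4, 10) == pytest.approx(4 / 120, rel=1e-10)


def test_tail_from_zero_is_one_and_single_draw_is_proportion():
    assert hypergeom_tail(0, 5, 3, 10) == 1.0
    assert hypergeom_tail(1, 1, 4, 10) == pytest.approx(0.4, rel=1e-12)


def test_tail_matches_exhaustive_enumeration_on_sample_grid():
    for N in (5, 8, 11):
        for n in range(N + 1):
            for K in range(N + 1):
                for k in range(min(n, K) + 1):
                    exact = float(hypergeom_tail_enum(k, n, K, N))
                    assert hypergeom_tail(k, n, K, N) == pytest.approx(exact, abs=1e-12)


def test_invalid_arguments_error():
    with pytest.raises(ValueError):
        hypergeom_tail(4, 3, 4, 10)
    with pytest.raises(ValueError):
        hypergeom_tail(1, 5, 11, 10)


def test_tail_monotone_in_k():
    values = [hypergeom_tail(k, 20, 30, 100) for k in range(0, 21)]
    assert all(a >= b for a, b in zip(values, values[1:]))


# ----------------------------------------------------------- GO enrichment

def test_enrichment_worked_example_single_term():
    population = [f"g{i}" for i in range(10)]
    gene2go = {g: {"T"} for g in population[:4]}
    study = population[:3]
    (res,) = go_enrichment(study, population, gene2go)
    assert res.p_raw == pytest.approx(4 / 120, rel=1e-9)
    assert res.p_bonferroni == pytest.approx(4 / 120, rel=1e-9)
    assert res.significant


def test_study_equal_to_population_gives_p_one():
    population = [f"g{i}" for i in range(6)]
    gene2go = {g: {"T1"} for g in population[:3]} | {g: {"T2"} for g in population[3:]}
    results = go_enrichment(population, population, gene2go)
    assert all(r.p_raw == pytest.approx(1.0) for r in results)


def test_bonferroni_multiplier_counts_tested_terms():
    population = [f"g{i}" for i in range(40)]
    gene2go = {}
    for g in population[:6]:
        gene2go.setdefault(g, set()).add("A")
    for g in population[3:9]:
        gene2go.setdefault(g, set()).add("B")
    study = population[:6]
    results = {r.term: r for r in go_enrichment(study, population, gene2go)}
    assert len(results) == 2
    for r in results.values():
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 2))
        assert r.p_bonferroni >= r.p_raw


def test_study_gene_outside_population_errors():
    with pytest.raises(ValueError, match="absent from population"):
        go_enrichment(["gX"], ["g1"], {})


def test_null_flag_rate_matches_direct_counting():
    # flag decisions on a random background equal an independent recount
    table = make_count_table(7, 5, 200, background="poisson", background_lambda=1.0)
    results = expansion_ratios(table, table.species)
    recount = 0
    for group in table.groups:
        row = table.counts.loc[group]
        mean = row.mean()
        if mean == 0:
            continue
        recount += int((row / mean >= 2.0).sum())
    assert sum(r.flagged for r in results) == recount
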
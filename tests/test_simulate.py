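"""Synthetic-data generators: determinism, truth consistency, calibration."""

import numpy as np
import pytest

from brettkit import (
    GenomeIndex,
    make_blast_table,
    make_codon_msa,
    make_count_table,
    make_rearranged_pair,
    sample_rearrangement_truth,
    simulate_snp_track,
    truth_to_alignments,
)
from brettkit.ani import ani_matrix
from brettkit.core import REVERSE
from brettkit.simulate import _revcomp


# ------------------------------------------------------- rearranged pairs

def test_no_events_gives_identical_genomes_and_one_segment():
    ref, qry, truth = make_rearranged_pair(1, [100_000], 0, 0)
    assert qry["qry_1"] == ref["ref_1"]
    (seg,) = truth.segment_map
    assert (seg.ref_start, seg.ref_end) == (0, 100_000)
    assert (seg.qry_start, seg.qry_end) == (0, 100_000)
    assert seg.orientation == "forward"


@pytest.mark.parametrize("nt,ni", [(1, 0), (0, 1), (1, 1)])
def test_segment_substrings_match_between_genomes(nt, ni):
    ref, qry, truth = make_rearranged_pair(7, [200_000, 160_000], nt, ni)
    for seg in truth.segment_map:
        expected = ref[seg.ref_contig][seg.ref_start:seg.ref_end]
        if seg.orientation == REVERSE:
            expected = _revcomp(expected)
        assert qry[seg.qry_contig][seg.qry_start:seg.qry_end] == expected


@pytest.mark.parametrize("nt,ni", [(0, 0), (1, 1)])
def test_segment_map_tiles_both_genomes(nt, ni):
    truth = sample_rearrangement_truth(3, [200_000, 160_000], nt, ni)
    for index, start_attr, end_attr, contig_attr in [
        (truth.ref_index, "ref_start", "ref_end", "ref_contig"),
        (truth.qry_index, "qry_start", "qry_end", "qry_contig"),
    ]:
        for contig, length in index:
            ivs = sorted(
                (getattr(s, start_attr), getattr(s, end_attr))
                for s in truth.segment_map if getattr(s, contig_attr) == contig
            )
            cursor = 0
            for s, e in ivs:
                assert s == cursor
                cursor = e
            assert cursor == length


def test_same_seed_gives_byte_identical_pair():
    a = make_rearranged_pair(12, [200_000], 1, 1)
    b = make_rearranged_pair(12, [200_000], 1, 1)
    assert a[0] == b[0] and a[1] == b[1]
    assert a[2].segment_map == b[2].segment_map


def test_contig_too_short_for_min_segment_errors():
    with pytest.raises(ValueError, match="4 \\* min_segment"):
        sample_rearrangement_truth(1, [50_000], 1, 0)


def test_truth_to_alignments_transcribes_segments():
    truth = sample_rearrangement_truth(2, [200_000], 0, 1)
    alignments = truth_to_alignments(truth)
    assert len(alignments) == len(truth.segment_map)
    assert all(a.identity_pct == 100.0 for a in alignments)
    assert all(a.aligned_length == a.ref_end - a.ref_start for a in alignments)
    reverse = [a for a in alignments if a.orientation == REVERSE]
    assert len(reverse) == 1  # exactly the inverted segment


# ------------------------------------------------------------ SNP mosaics

def test_zero_density_gives_zero_snps():
    index = GenomeIndex([("c1", 100_000)])
    (track,) = simulate_snp_track(1, index, [("c1", 0, 100_000, 0.0)])
    assert track.positions == []


def test_positions_stay_inside_their_regions():
    index = GenomeIndex([("c1", 200_000)])
    (track,) = simulate_snp_track(
        5, index, [("c1", 0, 50_000, 0.0), ("c1", 50_000, 150_000, 3.0),
                   ("c1", 150_000, 200_000, 0.0)])
    assert track.positions
    assert all(50_000 <= p < 150_000 for p in track.positions)


def test_snp_counts_follow_poisson_mean():
    # 100 kb at 3.2 SNPs/kb -> Poisson(320); check the replicate mean
    index = GenomeIndex([("c1", 100_000)])
    counts = [
        simulate_snp_track(seed, index, [("c1", 0, 100_000, 3.2)])[0].n_snps
        for seed in range(1000)
    ]
    se_of_mean = np.sqrt(320) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - 320) < 3 * se_of_mean


def test_non_tiling_plan_errors():
    index = GenomeIndex([("c1", 100_000)])
    with pytest.raises(ValueError, match="tile"):
        simulate_snp_track(1, index, [("c1", 0, 60_000, 1.0)])


# ------------------------------------------------------------ BLAST tables

def test_zero_hgt_fraction_means_all_native_labels():
    _, _, labels = make_blast_table(1, 50, 0.0)
    assert not any(labels.values())


def test_planted_hgt_proteins_have_positive_alien_index_sign():
    from brettkit.hgt import alien_index, best_hits

    table, _, labels = make_blast_table(3, 100, 0.2)
    for pid, (e_self, e_alien) in best_hits(table).items():
        ai = alien_index(e_self, e_alien)
        assert (ai > 0) == labels[pid]


def test_blast_table_deterministic():
    a = make_blast_table(9, 40, 0.1)
    b = make_blast_table(9, 40, 0.1)
    assert a[0].equals(b[0]) and a[1] == b[1] and a[2] == b[2]


# ------------------------------------------------------------ count tables

def test_planted_counts_land_exactly():
    table = make_count_table(1, 5, 10, planted=[("OG0000007", "sp1", 4)])
    assert table.counts.loc["OG0000007"].tolist() == [4, 1, 1, 1, 1]


def test_background_only_table_is_all_ones():
    table = make_count_table(1, 3, 5)
    assert (table.counts.values == 1).all()


# -------------------------------------------------------------- codon MSA

def test_identity_one_gives_identical_sequences():
    msa = make_codon_msa(1, 4, 100, 1.0)
    assert len(set(msa.values())) == 1


def test_pairwise_identity_tracks_target():
    msa = make_codon_msa(2, 4, 3000, 0.77)
    matrix = ani_matrix(msa)
    off_diag = [matrix.values[i, j]
                for i in range(4) for j in range(4) if i != j]
    assert all(75.0 <= v <= 79.0 for v in off_diag)


def test_gap_injection_preserves_identity_and_length():
    msa = make_codon_msa(3, 3, 2000, 0.9, gap_rate=0.05)
    assert {len(s) for s in msa.values()} == {6000}
    assert any("-" in s for s in msa.values())
    matrix = ani_matrix(msa)
    off_diag = [matrix.values[i, j] for i in range(3) for j in range(3) if i != j]
    assert all(88.0 <= v <= 92.0 for v in off_diag)


def test_msa_deterministic():
    assert make_codon_msa(4, 3, 500, 0.8) == make_codon_msa(4, 3, 500, 0.8)
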
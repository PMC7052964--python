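"""Window algorithm: windowing, pairing, merging, trimming, block counts."""

import pytest

from brettkit import (
    AlignmentRecord,
    GenomeIndex,
    SyntenyConfig,
    count_blocks,
    find_blocks,
    merge_and_trim,
    pair_windows,
    window_genome,
)
from brettkit.synteny import Window, WindowPair
from oracle import brute_force_blocks, enumerate_windows
from util import aln_tuples, block_tuples, blocks_for_truth


def identity_alignment(length, contig_r="r1", contig_q="q1"):
    return AlignmentRecord(contig_r, 0, length, contig_q, 0, length,
                           "forward", length, 100.0)


# -------------------------------------------------------------- windowing

@pytest.mark.parametrize("length,expected", [
    # final window of length == step is kept; shorter ones merge backwards
    (20_000, [(0, 20_000), (10_000, 20_000)]),
    (100_000, [(s, min(s + 20_000, 100_000)) for s in range(0, 100_000, 10_000)]),
    (5_000, [(0, 5_000)]),
    (25_000, [(0, 20_000), (10_000, 25_000)]),
])
def test_window_genome_tiling_rule(length, expected):
    wins = window_genome(GenomeIndex([("c", length)]))
    assert [(w.start, w.end) for w in wins] == expected


def test_window_genome_matches_loop_enumeration_oracle():
    contigs = [("a", 73_123), ("b", 9_999), ("c", 20_001)]
    wins = window_genome(GenomeIndex(contigs))
    assert [(w.contig_id, w.start, w.end) for w in wins] == \
        enumerate_windows(contigs, 20_000, 10_000)


def test_windows_cover_each_contig():
    for length in (10_000, 15_000, 33_333, 199_999):
        wins = window_genome(GenomeIndex([("c", length)]))
        assert wins[0].start == 0
        assert max(w.end for w in wins) == length
        assert all(w.length >= 1 for w in wins)


# ---------------------------------------------------------------- pairing

def test_identity_alignment_pairs_every_window_with_its_twin():
    index = GenomeIndex([("r1", 100_000)])
    qindex = GenomeIndex([("q1", 100_000)])
    cfg = SyntenyConfig()
    pairs = pair_windows([identity_alignment(100_000)],
                         window_genome(index, cfg), window_genome(qindex, cfg), cfg)
    diagonal = {(p.ref_window.start, p.qry_window.start) for p in pairs
                if p.ref_window.start == p.qry_window.start}
    assert len(diagonal) == 10  # one per window
    assert all(p.orientation == "forward" for p in pairs)
    full = [p for p in pairs if p.ref_window.start == p.qry_window.start
            and p.ref_window.length == 20_000]
    assert all(p.support_bp == 20_000 for p in full)


def test_single_offset_alignment_only_pairs_projected_windows():
    index = GenomeIndex([("r1", 100_000)])
    qindex = GenomeIndex([("q1", 100_000)])
    cfg = SyntenyConfig()
    aln = AlignmentRecord("r1", 0, 20_000, "q1", 50_000, 70_000, "forward", 20_000, 100.0)
    pairs = pair_windows([aln], window_genome(index, cfg), window_genome(qindex, cfg), cfg)
    assert all(p.qry_window.start < 70_000 and p.qry_window.end > 50_000 for p in pairs)
    assert all(p.ref_window.start < 20_000 for p in pairs)


def test_alignment_below_min_support_is_dropped():
    index = GenomeIndex([("r1", 40_000)])
    qindex = GenomeIndex([("q1", 40_000)])
    cfg = SyntenyConfig()
    aln = AlignmentRecord("r1", 2_000, 3_500, "q1", 2_000, 3_500, "forward", 1_500, 100.0)
    assert pair_windows([aln], window_genome(index, cfg),
                        window_genome(qindex, cfg), cfg) == []


def test_unknown_contig_in_alignment_errors():
    cfg = SyntenyConfig()
    wins = window_genome(GenomeIndex([("r1", 50_000)]), cfg)
    with pytest.raises(ValueError, match="unknown"):
        pair_windows([identity_alignment(50_000, contig_r="rX")], wins, wins, cfg)


# ---------------------------------------------------------- merge and trim

def test_identity_pair_merges_to_one_full_span_block():
    index = GenomeIndex([("r1", 100_000)])
    qindex = GenomeIndex([("q1", 100_000)])
    blocks = find_blocks([identity_alignment(100_000)], index, qindex)
    (block,) = blocks
    assert (block.ref_start, block.ref_end) == (0, 100_000)
    assert (block.qry_start, block.qry_end) == (0, 100_000)
    assert block.orientation == "forward"


def test_half_swap_truth_yields_two_blocks():
    # query = second half + first half of a 100 kb reference contig
    alns = [
        AlignmentRecord("r1", 0, 50_000, "q1", 50_000, 100_000, "forward", 50_000, 100.0),
        AlignmentRecord("r1", 50_000, 100_000, "q1", 0, 50_000, "forward", 50_000, 100.0),
    ]
    index = GenomeIndex([("r1", 100_000)])
    qindex = GenomeIndex([("q1", 100_000)])
    blocks = find_blocks(alns, index, qindex)
    assert len(blocks) == 2
    assert {b.orientation for b in blocks} == {"forward"}
    # reference intervals must not overlap after trimming
    assert blocks[0].ref_end <= blocks[1].ref_start


def test_single_inversion_yields_three_blocks_with_reverse_middle():
    alns = [
        AlignmentRecord("r1", 0, 20_000, "q1", 0, 20_000, "forward", 20_000, 100.0),
        AlignmentRecord("r1", 20_000, 40_000, "q1", 20_000, 40_000, "reverse", 20_000, 100.0),
        AlignmentRecord("r1", 40_000, 100_000, "q1", 40_000, 100_000, "forward", 60_000, 100.0),
    ]
    index = GenomeIndex([("r1", 100_000)])
    qindex = GenomeIndex([("q1", 100_000)])
    blocks = find_blocks(alns, index, qindex)
    assert [b.orientation for b in blocks] == ["forward", "reverse", "forward"]


def test_merge_and_trim_is_idempotent_on_its_own_output():
    for seed in range(6):
        result = blocks_for_truth(seed, [200_000], 1, 1)
        if result is None:
            continue
        _, blocks = result
        pairs = [p for b in blocks for p in b.pairs]
        again = merge_and_trim(pairs)
        assert [(b.ref_contig, b.ref_start, b.ref_end, b.qry_contig, b.orientation)
                for b in again] == \
               [(b.ref_contig, b.ref_start, b.ref_end, b.qry_contig, b.orientation)
                for b in blocks]


def test_blocks_never_overlap_on_reference_and_respect_genome_length():
    for seed in range(8):
        result = blocks_for_truth(seed, [200_000], 2, 1)
        if result is None:
            continue
        truth, blocks = result
        per_contig: dict[str, list] = {}
        for b in blocks:
            per_contig.setdefault(b.ref_contig, []).append(b)
        for contig, blist in per_contig.items():
            blist.sort(key=lambda b: b.ref_start)
            for a, b in zip(blist, blist[1:]):
                assert a.ref_end <= b.ref_start
            assert sum(b.ref_len for b in blist) <= truth.ref_index.length_of(contig)


def test_count_blocks_totals_and_per_contig():
    truth, blocks = blocks_for_truth(5, [100_000, 120_000], 0, 0)
    total, per_contig = count_blocks(blocks)
    assert total == 2
    assert per_contig == {"ref_1": 1, "ref_2": 1}
    assert count_blocks([]) == (0, {})


def test_blocks_match_brute_force_oracle_on_sample_instances():
    for seed in (0, 1, 2, 3):
        result = blocks_for_truth(seed, [180_000], 1, 1)
        if result is None:
            continue
        truth, blocks = result
        from brettkit import truth_to_alignments

        expected = brute_force_blocks(
            aln_tuples(truth_to_alignments(truth)),
            truth.ref_index.entries, truth.qry_index.entries)
        assert sorted(block_tuples(blocks)) == sorted(expected)
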
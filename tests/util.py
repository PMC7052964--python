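"""Small shared helpers for the test suite."""

from __future__ import annotations

from brettkit import find_blocks, sample_rearrangement_truth, truth_to_alignments


def aln_tuples(alignments):
    """AlignmentRecord list -> plain tuples for the brute-force oracle."""
    return [
        (a.ref_contig, a.ref_start, a.ref_end,
         a.qry_contig, a.qry_start, a.qry_end, a.orientation)
        for a in alignments
    ]


def block_tuples(blocks):
    return [
        (b.ref_contig, b.ref_start, b.ref_end,
         b.qry_contig, b.qry_start, b.qry_end,
         b.orientation, b.n_windows, b.support_bp)
        for b in blocks
    ]


def blocks_for_truth(seed, lengths, n_translocations, n_inversions, cfg=None):
    """Truth instance -> (truth, blocks) or None if events were unplaceable."""
    try:
        truth = sample_rearrangement_truth(seed, lengths, n_translocations, n_inversions)
    except RuntimeError:
        return None
    alignments = truth_to_alignments(truth)
    if cfg is None:
        blocks = find_blocks(alignments, truth.ref_index, truth.qry_index)
    else:
        blocks = find_blocks(alignments, truth.ref_index, truth.qry_index, cfg)
    return truth, blocks
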
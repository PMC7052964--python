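"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's data structures and algorithmic
shortcuts: windows are enumerated with plain loops, every
(alignment, ref window, qry window) triple is visited, chains are found as
connected components of an explicitly materialised concordance graph via
networkx, and the hypergeometric tail is obtained by enumerating draws.
They share only the declarative rules with the implementation under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import networkx as nx

FORWARD = "forward"
REVERSE = "reverse"


def enumerate_windows(contigs, window, step):
    """[(contig, start, end)] under the sliding-window rule, by plain loops."""
    out = []
    for contig, length in contigs:
        wins = []
        for start in range(0, length, step):
            wins.append((contig, start, min(start + window, length)))
        if len(wins) >= 2 and wins[-1][2] - wins[-1][1] < step:
            contig_, s, e = wins[-2]
            wins[-2] = (contig_, s, max(e, wins[-1][2]))
            wins.pop()
        out.extend(wins)
    return out


def brute_force_blocks(
    alignments,
    ref_contigs,
    qry_contigs,
    window=20_000,
    step=10_000,
    min_support=2_000,
    max_gap=1,
    diag_tol=None,
):
    """Blocks by exhaustive enumeration of the pair/merge/trim rules.

    ``alignments`` are tuples ``(ref_contig, ref_start, ref_end,
    qry_contig, qry_start, qry_end, orientation)`` in 0-based half-open
    coordinates; contigs are ``(name, length)`` lists.  Returns a list of
    ``(ref_contig, ref_start, ref_end, qry_contig, qry_start, qry_end,
    orientation, n_windows, support_bp)`` tuples.
    """
    if diag_tol is None:
        diag_tol = step
    ref_windows = enumerate_windows(ref_contigs, window, step)
    qry_windows = enumerate_windows(qry_contigs, window, step)

    # -- pairing: visit every triple ------------------------------------
    acc = {}
    for (rc, rs, re_, qc, qs, qe, orient) in alignments:
        scale = (qe - qs) / (re_ - rs)
        for rw in ref_windows:
            if rw[0] != rc or rw[1] >= re_ or rw[2] <= rs:
                continue
            ov_start = max(rw[1], rs)
            ov_end = min(rw[2], re_)
            if orient == FORWARD:
                q0 = qs + (ov_start - rs) * scale
                q1 = qs + (ov_end - rs) * scale
            else:
                q0 = qe - (ov_end - rs) * scale
                q1 = qe - (ov_start - rs) * scale
            for qw in qry_windows:
                if qw[0] != qc:
                    continue
                c0, c1 = max(q0, float(qw[1])), min(q1, float(qw[2]))
                bp = c1 - c0
                if bp <= 0:
                    continue
                q_mid = (c0 + c1) / 2.0
                if orient == FORWARD:
                    r_mid = rs + (q_mid - qs) / scale
                    r_lo = rs + (c0 - qs) / scale
                    r_hi = rs + (c1 - qs) / scale
                else:
                    r_mid = rs + (qe - q_mid) / scale
                    r_lo = rs + (qe - c1) / scale
                    r_hi = rs + (qe - c0) / scale
                key = (rw, qw, orient)
                if key not in acc:
                    acc[key] = [0.0, 0.0, 0.0, float("inf"), float("-inf"),
                                float("inf"), float("-inf")]
                e = acc[key]
                e[0] += bp
                e[1] += bp * q_mid
                e[2] += bp * r_mid
                e[3] = min(e[3], r_lo)
                e[4] = max(e[4], r_hi)
                e[5] = min(e[5], c0)
                e[6] = max(e[6], c1)
    pairs = []
    for (rw, qw, orient), (bp, q_sum, r_sum, r_lo, r_hi, q_lo, q_hi) in acc.items():
        if bp >= min_support:
            pairs.append({
                "rw": rw, "qw": qw, "orient": orient,
                "support": int(round(bp)),
                "r_anchor": r_sum / bp, "q_anchor": q_sum / bp,
                "r_sup": (r_lo, r_hi), "q_sup": (q_lo, q_hi),
            })

    # -- merging: explicit concordance graph ----------------------------
    def conc(p, q):
        if p["orient"] != q["orient"]:
            return False
        if p["rw"][0] != q["rw"][0] or p["qw"][0] != q["qw"][0]:
            return False
        tol = max_gap * step
        if p["r_sup"][0] > q["r_sup"][1] + tol or q["r_sup"][0] > p["r_sup"][1] + tol:
            return False
        if p["q_sup"][0] > q["q_sup"][1] + tol or q["q_sup"][0] > p["q_sup"][1] + tol:
            return False
        if p["orient"] == FORWARD:
            diag_p = p["q_anchor"] - p["r_anchor"]
            diag_q = q["q_anchor"] - q["r_anchor"]
        else:
            diag_p = p["q_anchor"] + p["r_anchor"]
            diag_q = q["q_anchor"] + q["r_anchor"]
        if abs(diag_p - diag_q) > diag_tol:
            return False
        dr = q["r_anchor"] - p["r_anchor"]
        dq = q["q_anchor"] - p["q_anchor"]
        return dr * dq >= 0 if p["orient"] == FORWARD else dr * dq <= 0

    graph = nx.Graph()
    graph.add_nodes_from(range(len(pairs)))
    for i, j in itertools.combinations(range(len(pairs)), 2):
        if conc(pairs[i], pairs[j]):
            graph.add_edge(i, j)
    blocks = []
    for component in nx.connected_components(graph):
        members = [pairs[i] for i in component]
        blocks.append([
            members[0]["rw"][0],
            min(m["rw"][1] for m in members),
            max(m["rw"][2] for m in members),
            members[0]["qw"][0],
            min(m["qw"][1] for m in members),
            max(m["qw"][2] for m in members),
            members[0]["orient"],
            len({m["rw"] for m in members}),
            sum(m["support"] for m in members),
        ])

    # -- trimming: canonical first-overlap fixpoint ----------------------
    def key(b):
        return (b[0], b[1], b[2], b[3], b[4], b[6])

    blocks.sort(key=key)
    while True:
        clash = None
        for i, j in itertools.combinations(range(len(blocks)), 2):
            a, b = blocks[i], blocks[j]
            if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                clash = (a, b)
                break
        if clash is None:
            break
        a, b = clash
        loser = a if b[8] > a[8] else b  # ties: later block loses
        winner = b if loser is a else a
        if loser[1] < winner[1]:
            loser[2] = winner[1]
        else:
            loser[1] = winner[2]
        blocks = sorted((x for x in blocks if x[2] - x[1] >= 1), key=key)
    return [tuple(b) for b in blocks]


def hypergeom_tail_enum(k, n, K, N):
    """P(X >= k) by enumerating every size-n draw from an N population.

    Items 0..K-1 are marked.  Exact rational arithmetic; feasible for
    N <= 12.
    """
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for item in draw if item < K) >= k:
            hits += 1
    return Fraction(hits, total)
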
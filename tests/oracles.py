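"""Independent oracles used to cross-check the implementation.

Each oracle recomputes a quantity by a different route than the package
uses: exhaustive enumeration, memoized recursion written from the
recurrence definition, graph connected components, or literal 2^n
enumeration.  They are deliberately slow and simple.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, product

import networkx as nx
import numpy as np


def glocal_oracle(motif: str, window: str, match: float = 5.0,
                  mismatch: float = -4.0, gap_open: float = 10.0,
                  gap_extend: float = 0.5) -> tuple[float, int]:
    """Memoized-recursion glocal optimum: (score, matches), lexicographic.

    Motif is global; leading/trailing window bases are free; a gap of
    length L costs gap_open + L*gap_extend.  States: 0 = after a
    substitution column (or at the start), 1 = inside a motif-vs-gap
    run, 2 = inside a window-vs-gap run.
    """
    m, n = len(motif), len(window)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> tuple[float, int]:
        if i == m:
            return (0.0, 0)  # remaining window is a free end gap
        cands = []
        if j < n:
            if motif[i] == window[j] and motif[i] in "ACGT":
                gain, ident = match, 1
            else:
                gain, ident = mismatch, 0
            s, mm = best(i + 1, j + 1, 0)
            cands.append((s + gain, mm + ident))
        cost = gap_extend if state == 1 else gap_open + gap_extend
        s, mm = best(i + 1, j, 1)
        cands.append((s - cost, mm))
        if j < n and i > 0:
            cost = gap_extend if state == 2 else gap_open + gap_extend
            s, mm = best(i, j + 1, 2)
            cands.append((s - cost, mm))
        return max(cands)

    return max(best(0, j, 0) for j in range(n + 1))


def ungapped_oracle(motif: str, window: str, match: float = 5.0,
                    mismatch: float = -4.0) -> tuple[float, int]:
    """Best ungapped placement over all offsets: (score, matches)."""
    m = len(motif)
    best = (-np.inf, -1)
    for off in range(len(window) - m + 1):
        seg = window[off:off + m]
        ident = sum(1 for a, b in zip(motif, seg) if a == b and a in "ACGT")
        best = max(best, (ident * match + (m - ident) * mismatch, ident))
    return best


def enumerate_alignments_oracle(motif: str, window: str,
                                match: float = 5.0, mismatch: float = -4.0,
                                gap_open: float = 10.0,
                                gap_extend: float = 0.5) -> tuple[float, int]:
    """Literal enumeration of every monotone alignment (tiny inputs only).

    An alignment is a strictly increasing partial mapping of motif
    positions to window positions; unmapped motif positions form
    motif-vs-gap runs (always charged), and skipped window positions
    between the first and last mapped window position form
    window-vs-gap runs (charged); window bases outside that span are
    free end gaps.  Scores every mapping from scratch.
    """
    m, n = len(motif), len(window)
    assert m <= 8 and n <= 14, "enumeration oracle is for tiny instances"

    def gap_cost(length: int) -> float:
        return gap_open + length * gap_extend if length else 0.0

    # the fully-gapped motif (no aligned column) is a legal alignment
    best = (-gap_cost(m), 0)
    # choose which motif positions are aligned, and to which window positions
    for aligned_mask in product([0, 1], repeat=m):
        k = sum(aligned_mask)
        if k == 0:
            continue  # handled above
        idx = [i for i in range(m) if aligned_mask[i]]
        for cols in combinations(range(n), k):
            score, ident = 0.0, 0
            # substitution columns
            for i, j in zip(idx, cols):
                if motif[i] == window[j] and motif[i] in "ACGT":
                    score += match
                    ident += 1
                else:
                    score += mismatch
            # motif-vs-gap runs (including runs at the motif's ends)
            run = 0
            for i in range(m):
                if aligned_mask[i]:
                    score -= gap_cost(run)
                    run = 0
                else:
                    run += 1
            score -= gap_cost(run)
            # window-vs-gap runs strictly between mapped window columns
            for (i0, j0), (i1, j1) in zip(zip(idx, cols), zip(idx[1:], cols[1:])):
                interior = j1 - j0 - 1
                # interior window bases not consumed by motif gaps: when
                # both flanking columns are substitutions the skipped
                # window bases form one charged run
                if interior and i1 - i0 - 1 == 0:
                    score -= gap_cost(interior)
                elif interior and i1 - i0 - 1 > 0:
                    # both a motif gap and a window gap between anchors:
                    # motif run already charged above; window run charged too
                    score -= gap_cost(interior)
            best = max(best, (score, ident))
    return best


def single_linkage_oracle(positions_by_key: dict, window: int) -> list[set]:
    """All-pairs single-linkage clustering via graph components.

    ``positions_by_key`` maps (sample, contig) -> list of positions.
    Returns the clusters as sets of (sample, contig, index) labels.
    """
    g = nx.Graph()
    for key, positions in positions_by_key.items():
        for i, p in enumerate(positions):
            g.add_node((key, i, p))
            for j, q in enumerate(positions):
                if i < j and abs(p - q) <= window:
                    g.add_edge((key, i, p), (key, j, q))
    return [set(c) for c in nx.connected_components(g)]


def wilcoxon_enumeration_oracle(diffs) -> float:
    """Literal 2^n enumeration of sign assignments (n <= 15)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    assert 1 <= n <= 15
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    e_w = ranks.sum() / 2
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - e_w) >= abs(w_obs - e_w) - 1e-9:
            count += 1
    return count / 2.0 ** n


def overlap_oracle(a_intervals, b_intervals, slop: int) -> int:
    """Count of A intervals overlapping any B interval after padding each."""
    shared = 0
    for ca, sa, ea in a_intervals:
        hit = False
        for cb, sb, eb in b_intervals:
            if ca == cb and sa - slop < eb + slop and sb - slop < ea + slop:
                hit = True
        shared += hit
    return shared
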
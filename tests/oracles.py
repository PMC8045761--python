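"""Independent reference implementations used only to cross-check the package.

Each oracle recomputes a quantity by a different route than the library:
textbook formulas written out by hand, exhaustive enumeration, or naive
O(n^3) algorithms. They are deliberately slow and simple.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

_STOPS = {"TAA", "TAG", "TGA"}


def welch_pvalue(a, b) -> float:
    """Two-sided Welch t-test p-value from the textbook statistic and
    Welch-Satterthwaite degrees of freedom."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(2 * stats.t.sf(abs(t), df))


def bh_stepup(p_values) -> list[float]:
    """Brute-force Benjamini-Hochberg: q_i = min over j with p_j >= p_i of
    p_(j) * m / rank(j), computed from the explicit definition."""
    p = [float(x) for x in p_values]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    for rank_i in range(m):
        q = min(
            p[order[rank_j]] * m / (rank_j + 1) for rank_j in range(rank_i, m)
        )
        q_sorted[rank_i] = min(q, 1.0)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out


def uorf_scan(utr5: str, cds: str, mode: str):
    """Exhaustive triplet-walk uORF scanner, built from codon lists.

    Returns tuples (start, stop_offset_or_None, contained, length_codons)
    sorted by start offset.
    """
    utr5, cds = utr5.upper(), cds.upper()
    full = utr5 + cds
    found = []
    for start in range(len(utr5)):
        if start + 3 > len(utr5):
            break
        if utr5[start : start + 3] != "ATG":
            continue
        codons = [full[j : j + 3] for j in range(start, len(full) - 2, 3)]
        codons = [c for c in codons if len(c) == 3]
        stop_idx = None
        for k, codon in enumerate(codons[1:], start=1):
            if codon in _STOPS:
                stop_idx = k
                break
        if stop_idx is not None:
            stop_offset = start + 3 * stop_idx
            contained = stop_offset + 3 <= len(utr5)
            length = stop_idx
        else:
            stop_offset = None
            contained = False
            length = len(codons)
        if mode == "CONTAINED" and not contained:
            continue
        found.append((start, stop_offset, contained, length))
    return found


def _cluster_distance(members_a, members_b, dmat, linkage: str) -> float:
    vals = [dmat[i, j] for i in members_a for j in members_b]
    if linkage == "AVERAGE":
        return sum(vals) / len(vals)
    if linkage == "COMPLETE":
        return max(vals)
    return min(vals)


def naive_agglomerate(dmat: np.ndarray, linkage: str):
    """O(n^3) agglomeration recomputing every cluster distance from the
    original pairwise matrix at every step. Ties break toward the pair whose
    smallest (then next-smallest) original member indices sort lowest.

    Returns merges as (left_node, right_node, height) with scipy-style node
    ids and the left-first leaf order.
    """
    n = dmat.shape[0]
    clusters = {i: [i] for i in range(n)}  # node id -> original members
    node_of = list(range(n))
    active = list(range(n))
    children = {}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                i, j = active[x], active[y]
                d = _cluster_distance(clusters[i], clusters[j], dmat, linkage)
                ri, rj = min(clusters[i]), min(clusters[j])
                key = (d, min(ri, rj), max(ri, rj))
                if best is None or key < best[0]:
                    best = (key, i, j, d)
        _, i, j, d = best
        left, right = (i, j) if min(clusters[i]) < min(clusters[j]) else (j, i)
        merges.append((left, right, d))
        children[next_id] = (left, right)
        clusters[next_id] = clusters[i] + clusters[j]
        active = [a for a in active if a not in (i, j)] + [next_id]
        next_id += 1

    def leaves(node):
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    return merges, leaves(next_id - 1)
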
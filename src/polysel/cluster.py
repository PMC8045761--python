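"""Row standardization and deterministic agglomerative clustering for heatmaps.

Gene rows are log2-transformed with a pseudocount and z-scored so that the
display emphasizes pattern rather than magnitude. Clustering is agglomerative
with Pearson-correlation distance (1 - r) and average linkage by default —
the common heatmap convention — with fully specified determinism: ties are
broken toward the pair containing the lowest original row indices, and the
leaf order comes from a left-first traversal of the merge tree.

The agglomeration uses Lance-Williams distance updates, so average linkage is
the unweighted mean of all original pairwise distances between the two groups
(UPGMA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMetric",
    "Linkage",
    "ClusterResult",
    "log_zscore",
    "pairwise_distance",
    "hcluster",
]


class DistanceMetric(str, Enum):
    PEARSON = "PEARSON"
    EUCLIDEAN = "EUCLIDEAN"


class Linkage(str, Enum):
    AVERAGE = "AVERAGE"
    COMPLETE = "COMPLETE"
    SINGLE = "SINGLE"


@dataclass
class ClusterResult:
    """Merge tree and leaf order. Leaves are 0..n-1; internal nodes n, n+1, ...

    Each merge is (left_node, right_node, height); the left node is the one
    whose earliest original leaf index is smaller. ``leaf_order`` lists row
    indices in display order; ``leaf_labels`` the corresponding labels when
    row labels were supplied.
    """

    leaf_order: list[int]
    merges: list[tuple[int, int, float]]
    distance: DistanceMetric
    linkage: Linkage
    labels: list[str] | None = None

    @property
    def leaf_labels(self) -> list[str] | None:
        if self.labels is None:
            return None
        return [self.labels[i] for i in self.leaf_order]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "distance": self.distance.value,
            "linkage": self.linkage.value,
            "leaf_order": self.leaf_order,
            "leaf_labels": self.leaf_labels,
            "merges": [[a, b, h] for a, b, h in self.merges],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def log_zscore(values: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Per-row log2(x + pseudocount) then z-score; constant rows map to zeros.

    The standard deviation is the population one (ddof = 0).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = np.log2(np.asarray(values, dtype=float) + pseudocount)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mean, sd, out=out, where=sd > 0)
    return out


def pairwise_distance(
    values: np.ndarray, metric: DistanceMetric = DistanceMetric.PEARSON
) -> np.ndarray:
    """Square distance matrix between rows.

    PEARSON is 1 - Pearson correlation (range [0, 2]); rows with zero variance
    are at distance 0 from identical rows and 1 from everything else.
    """
    metric = DistanceMetric(metric)
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    if metric is DistanceMetric.EUCLIDEAN:
        return squareform(pdist(x, metric="euclidean"))
    sd = x.std(axis=1, ddof=0)
    dist = np.ones((n, n))
    ok = sd > 0
    if ok.any():
        sub = x[ok]
        r = np.corrcoef(sub)
        dist[np.ix_(ok, ok)] = np.clip(1.0 - r, 0.0, 2.0)
    # degenerate rows: distance 0 only to bitwise-identical rows
    flat = np.where(~ok)[0]
    for i in flat:
        for j in range(n):
            dist[i, j] = dist[j, i] = 0.0 if np.array_equal(x[i], x[j]) else 1.0
    np.fill_diagonal(dist, 0.0)
    return dist


def hcluster(
    values: np.ndarray,
    distance: DistanceMetric = DistanceMetric.PEARSON,
    linkage: Linkage = Linkage.AVERAGE,
    labels: list[str] | None = None,
) -> ClusterResult:
    """Agglomerative clustering of rows with deterministic tie-breaking.

    At each step the active pair with minimal linkage distance merges; among
    exact ties the pair whose (smallest, next) original leaf indices sort
    lowest wins. Inter-cluster distances follow Lance-Williams updates for the
    chosen linkage.
    """
    distance = DistanceMetric(distance)
    linkage = Linkage(linkage)
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("hcluster needs at least 2 rows")
    if labels is not None and len(labels) != n:
        raise ValueError("labels length must match number of rows")

    d = pairwise_distance(x, distance)
    node_id = list(range(n))  # active cluster -> tree node id
    rep = list(range(n))  # smallest original leaf index per active cluster
    size = [1] * n
    active = list(range(n))
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float]] = []
    next_id = n

    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = d[i, j]
                key = (dij, min(rep[i], rep[j]), max(rep[i], rep[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        height = d[i, j]
        left, right = (i, j) if rep[i] < rep[j] else (j, i)
        children[next_id] = (node_id[left], node_id[right])
        merges.append((node_id[left], node_id[right], float(height)))

        # Lance-Williams update into slot i; retire j
        for k in active:
            if k in (i, j):
                continue
            if linkage is Linkage.AVERAGE:
                dnew = (size[i] * d[i, k] + size[j] * d[j, k]) / (size[i] + size[j])
            elif linkage is Linkage.COMPLETE:
                dnew = max(d[i, k], d[j, k])
            else:
                dnew = min(d[i, k], d[j, k])
            d[i, k] = d[k, i] = dnew
        size[i] += size[j]
        rep[i] = min(rep[i], rep[j])
        node_id[i] = next_id
        active.remove(j)
        next_id += 1

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return _leaves(a) + _leaves(b)

    leaf_order = _leaves(next_id - 1)
    return ClusterResult(
        leaf_order=leaf_order,
        merges=merges,
        distance=distance,
        linkage=linkage,
        labels=labels,
    )
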
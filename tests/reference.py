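"""Independent O(n^2) reference implementations used as test oracles.

These deliberately avoid the package's accelerated code paths (and
scikit-learn / scipy tree structures): DBSCAN is a plain BFS over an
exhaustively computed closed-ball adjacency matrix, and nearest-neighbour
search is exhaustive pairwise minimisation.
"""

from __future__ import annotations

import numpy as np


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN by exhaustive adjacency + breadth-first expansion.

    Conventions: a point's neighbourhood is the closed ball (distance
    <= eps) and includes the point itself; clusters are numbered 0, 1, ...
    in order of first appearance in the input; noise is -1.  Points are
    visited in index order and border points attach to the first cluster
    that reaches them, as in the standard sequential algorithm.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    adjacency = dist <= eps
    core = adjacency.sum(axis=1) >= min_pts

    next_label = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = next_label
        queue = [i]
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in np.flatnonzero(adjacency[j]):
                if labels[k] == -1:
                    labels[k] = next_label
                    queue.append(int(k))
        next_label += 1

    # canonical renumbering in first-appearance order
    out = np.full(n, -1, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def brute_nn(
    source_xy: np.ndarray,
    target_xy: np.ndarray,
    target_ids: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive nearest-target search with lowest-id tie-breaking.

    Returns (nearest_target_id, distance) per source point.
    """
    src = np.asarray(source_xy, dtype=float).reshape(-1, 2)
    tgt = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    ids = np.asarray(target_ids)
    out_ids = np.empty(len(src), dtype=ids.dtype)
    out_d = np.empty(len(src))
    for i, p in enumerate(src):
        d = np.hypot(tgt[:, 0] - p[0], tgt[:, 1] - p[1])
        dmin = d.min()
        candidates = ids[d == dmin]
        out_ids[i] = candidates.min()
        out_d[i] = dmin
    return out_ids, out_d


def brute_histogram(
    distances: np.ndarray, bin_width: float, lo: float, n_bins: int
) -> np.ndarray:
    """Recount into [lo + k*w, lo + (k+1)*w) bins by explicit comparison."""
    counts = np.zeros(n_bins, dtype=np.int64)
    for d in np.asarray(distances, dtype=float):
        for k in range(n_bins):
            if lo + k * bin_width <= d < lo + (k + 1) * bin_width:
                counts[k] += 1
                break
    return counts
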
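"""Centroid clustering and cross-colour nearest-neighbour geometry.

Trace centroids of each colour are clustered independently with DBSCAN
(defaults: eps = 150 nm, min_pts = 10, where min_pts counts the point
itself and "within eps" is the closed ball, distance <= eps).  Each
cluster is summarised by the unweighted mean of its member centroids, and
for every cluster of one colour the distance to the nearest cluster of the
other colour is found with a K-D tree; the distances are binned into a
left-closed right-open histogram whose mode estimates the inter-molecular
contact distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

__all__ = [
    "CentroidCluster",
    "NNResult",
    "Histogram",
    "dbscan",
    "cluster_centres",
    "cross_colour_nn",
    "nn_histogram",
]

EPS_NM = 150.0
MIN_PTS = 10
NOISE = -1


@dataclass(frozen=True)
class CentroidCluster:
    """One DBSCAN cluster of trace centroids of a single colour."""

    cluster_id: int
    colour: str
    centre: tuple[float, float]
    size: int
    member_trace_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class Histogram:
    """Left-closed right-open binning of NN distances plus summary stats."""

    bin_edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray  # length n_bins
    n: int
    mean: float
    median: float
    modal_bin_left: float  # left edge of the most-populated bin; NaN if empty

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_nm": self.bin_edges[:-1],
                "bin_right_nm": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class NNResult:
    """Cross-colour nearest-neighbour distances for one direction.

    ``pairs`` has one row per source cluster: ``source_colour,
    source_cluster_id, nn_cluster_id, distance_nm``.
    """

    pairs: pd.DataFrame
    direction: str  # "a2b", "b2a" or "both"

    @property
    def distances(self) -> np.ndarray:
        return self.pairs["distance_nm"].to_numpy()


def dbscan(
    points: np.ndarray, eps: float = EPS_NM, min_pts: int = MIN_PTS
) -> np.ndarray:
    """DBSCAN labels for 2-D points; noise is -1.

    A core point has at least ``min_pts`` neighbours within ``eps``
    including itself; "within" is the closed ball (distance exactly eps
    counts).  Labels are canonicalised to first-occurrence order so the
    output is invariant (not merely equal up to permutation) under input
    reordering of the same point set.
    """
    if eps <= 0 or min_pts < 1:
        raise ValueError("require eps > 0 and min_pts >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.empty(0, dtype=np.int64)
    raw = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    return _canonical_labels(raw)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 0, 1, ... in order of first appearance."""
    out = np.full(len(labels), NOISE, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_centres(
    points: np.ndarray,
    labels: np.ndarray,
    colour: str,
    trace_ids: np.ndarray | None = None,
) -> list[CentroidCluster]:
    """One :class:`CentroidCluster` per non-noise label; centre is the
    unweighted mean of member points.  Ordered by cluster id."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels)
    out: list[CentroidCluster] = []
    for lab in np.unique(labels):
        if lab == NOISE:
            continue
        mask = labels == lab
        centre = pts[mask].mean(axis=0)
        members: tuple[str, ...] = ()
        if trace_ids is not None:
            members = tuple(np.asarray(trace_ids)[mask].tolist())
        out.append(
            CentroidCluster(
                cluster_id=int(lab),
                colour=colour,
                centre=(float(centre[0]), float(centre[1])),
                size=int(mask.sum()),
                member_trace_ids=members,
            )
        )
    return out


def _nn_one_direction(
    sources: list[CentroidCluster], targets: list[CentroidCluster]
) -> pd.DataFrame:
    """Nearest opposite-colour cluster for each source cluster.

    K-D-tree accelerated, with exact tie-breaking: among targets at the
    minimum distance the lowest cluster_id wins.  Distances are recomputed
    in plain array arithmetic so the result equals exhaustive pairwise
    minimisation exactly.
    """
    if not targets:
        raise ValueError("no opposite-colour clusters")
    t_xy = np.array([c.centre for c in targets])
    t_ids = np.array([c.cluster_id for c in targets])
    # sort targets by id so ties resolve to the lowest cluster_id
    order = np.argsort(t_ids, kind="stable")
    t_xy, t_ids = t_xy[order], t_ids[order]
    tree = cKDTree(t_xy)
    rows = []
    for src in sources:
        p = np.asarray(src.centre)
        d_tree, _ = tree.query(p, k=1)
        # gather every target at (numerically) the minimum distance
        cand = tree.query_ball_point(p, r=d_tree * (1 + 1e-12) + 1e-12)
        dists = np.hypot(t_xy[cand, 0] - p[0], t_xy[cand, 1] - p[1])
        dmin = dists.min()
        at_min = [cand[i] for i in np.flatnonzero(dists == dmin)]
        best = min(at_min, key=lambda i: t_ids[i])
        rows.append(
            (src.colour, src.cluster_id, int(t_ids[best]), float(dmin))
        )
    return pd.DataFrame(
        rows,
        columns=["source_colour", "source_cluster_id", "nn_cluster_id",
                 "distance_nm"],
    )


def cross_colour_nn(
    clusters_a: list[CentroidCluster],
    clusters_b: list[CentroidCluster],
    direction: str = "a2b",
) -> NNResult:
    """Cross-colour nearest-neighbour distances between cluster centres.

    ``direction`` is ``"a2b"`` (each A cluster to its nearest B), ``"b2a"``
    or ``"both"`` (union of the two).  Raises ``ValueError`` when the
    required opposite-colour set is empty.
    """
    if direction not in ("a2b", "b2a", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    frames = []
    if direction in ("a2b", "both"):
        if not clusters_a:
            raise ValueError("no source clusters for direction a2b")
        frames.append(_nn_one_direction(clusters_a, clusters_b))
    if direction in ("b2a", "both"):
        if not clusters_b:
            raise ValueError("no source clusters for direction b2a")
        frames.append(_nn_one_direction(clusters_b, clusters_a))
    return NNResult(pairs=pd.concat(frames, ignore_index=True), direction=direction)


def nn_histogram(
    distances: np.ndarray,
    bin_width: float = 5.0,
    hist_range: tuple[float, float] | None = None,
) -> Histogram:
    """Bin distances into [k*w, (k+1)*w) bins; counts sum to len(distances).

    With ``hist_range=None`` the bins start at 0 and extend to cover the
    largest distance.  An explicit range must cover every distance,
    otherwise the count-conservation invariant would silently break.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = np.asarray(distances, dtype=float)
    if hist_range is None:
        lo = 0.0
        hi = bin_width if len(d) == 0 else (np.floor(d.max() / bin_width) + 1) * bin_width
    else:
        lo, hi = map(float, hist_range)
        if len(d) and (d.min() < lo or d.max() >= hi):
            raise ValueError("explicit histogram range must cover all distances")
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.floor((d - lo) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins) if len(d) else np.zeros(n_bins, int)
    modal = float(edges[int(np.argmax(counts))]) if len(d) else float("nan")
    return Histogram(
        bin_edges=edges,
        counts=counts.astype(np.int64),
        n=len(d),
        mean=float(d.mean()) if len(d) else float("nan"),
        median=float(np.median(d)) if len(d) else float("nan"),
        modal_bin_left=modal,
    )
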
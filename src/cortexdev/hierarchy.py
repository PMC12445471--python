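"""Geodesic-distance hierarchy axes on cortical surface meshes.

The sensorimotor-to-association position of each parcel is proxied by the
minimum shortest-path distance along the mesh edge graph from a set of seed
vertices placed inside an association-like (DMN) region: larger distance means
more sensorimotor-like.  Parcels are partitioned into three near-equal-size
hierarchy groups by their axis rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import dijkstra
from sklearn.cluster import KMeans

from .mesh import SurfaceMesh

__all__ = [
    "HierarchyAxis",
    "geodesic_distances",
    "select_seed_vertices",
    "parcel_hierarchy",
    "tripartition",
    "best_overlap_mapping",
    "axis_correlation",
]

log = logging.getLogger(__name__)

GROUPS = ("sensorimotor", "middle", "association")


@dataclass
class HierarchyAxis:
    """Per-parcel axis scores and tripartite hierarchy groups.

    ``table`` is indexed by parcel id with columns ``score`` and (after
    :func:`tripartition`) ``group``.  ``source`` records provenance
    (``geodesic`` or ``external``); ``orientation`` states which direction of
    the score points toward association cortex.
    """

    table: pd.DataFrame
    source: str = "geodesic"
    orientation: str = "low_score_is_association"

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def sa_rank(self) -> pd.Series:
        """Normalized rank in [0, 1], 0 = sensorimotor end, 1 = association end."""
        s = self.scores
        ascending = self.orientation == "high_score_is_association"
        r = s.rank(method="first", ascending=ascending) - 1
        return r / max(len(s) - 1, 1)


def geodesic_distances(mesh: SurfaceMesh, seeds) -> np.ndarray:
    """Shortest-path distance from each vertex to its nearest seed vertex.

    Distances are along the mesh edge graph with Euclidean edge weights
    (graph approximation to the surface geodesic).  Zero exactly on seeds.
    """
    seeds = np.asarray(list(seeds), dtype=np.int64)
    if seeds.size == 0:
        raise ValueError("seed set must be non-empty")
    if seeds.min() < 0 or seeds.max() >= mesh.n_vertices:
        raise ValueError("seed index out of range")
    d = dijkstra(mesh.edge_graph(), directed=False, indices=seeds, min_only=True)
    if np.any(np.isinf(d)):
        warnings.warn(
            f"{int(np.isinf(d).sum())} vertices unreachable from seeds "
            "(disconnected mesh); their distance is inf"
        )
    return d


def select_seed_vertices(
    mesh: SurfaceMesh,
    region_mask,
    n_clusters: int,
    fraction: float,
    seed: int,
) -> np.ndarray:
    """Pick seed vertices inside a region by k-means cluster subsampling.

    Region vertices are clustered on their 3D coordinates into ``n_clusters``
    clusters; a uniformly random ``ceil(fraction * n_clusters)`` subset of
    clusters is retained and each contributes its member vertex nearest the
    cluster centroid.
    """
    region = np.asarray(list(region_mask), dtype=np.int64)
    if region.size == 0:
        raise ValueError("region mask must be non-empty")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if n_clusters > region.size:
        raise ValueError("n_clusters exceeds region size")
    coords = mesh.vertices[region]
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=4).fit(coords)
    n_keep = int(np.ceil(fraction * n_clusters))
    rng = np.random.default_rng(seed)
    kept = rng.choice(n_clusters, size=n_keep, replace=False)
    out = []
    for c in kept:
        members = np.where(km.labels_ == c)[0]
        d = np.linalg.norm(coords[members] - km.cluster_centers_[c], axis=1)
        out.append(region[members[np.argmin(d)]])
    return np.sort(np.asarray(out, dtype=np.int64))


def parcel_hierarchy(
    mesh: SurfaceMesh, parcellation, vertex_distance
) -> HierarchyAxis:
    """Average per-vertex geodesic distances within each parcel.

    Larger score = farther from the association seeds (more sensorimotor-like).
    """
    labels = np.asarray(parcellation)
    d = np.asarray(vertex_distance, dtype=float)
    if len(labels) != mesh.n_vertices or len(d) != mesh.n_vertices:
        raise ValueError("parcellation and distances must cover every vertex")
    parcels = np.unique(labels)
    scores = {}
    for p in parcels:
        members = labels == p
        if not members.any():
            raise ValueError(f"parcel {p} has no vertices")
        scores[p] = float(d[members].mean())
    table = pd.DataFrame({"score": pd.Series(scores)})
    table.index.name = "parcel_id"
    return HierarchyAxis(table=table, source="geodesic")


def tripartition(axis: HierarchyAxis, ordering: str = "descending") -> HierarchyAxis:
    """Split parcels into sensorimotor / middle / association thirds.

    Parcels are sorted by sensorimotor-to-association rank (``ordering``
    states whether ascending score runs toward association or away from it);
    the first third becomes sensorimotor, then middle, then association, with
    the ``n mod 3`` remainder parcels absorbed by the earlier groups so group
    sizes differ by at most one.  Score ties are broken by parcel id.
    """
    if ordering not in ("ascending", "descending"):
        raise ValueError("ordering must be 'ascending' or 'descending'")
    n = len(axis.table)
    if n < 3:
        raise ValueError("tripartition needs at least 3 parcels")
    tab = axis.table.copy()
    key = tab["score"] if ordering == "ascending" else -tab["score"]
    order = np.lexsort((tab.index.to_numpy(), key.to_numpy()))
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    group = np.empty(n, dtype=object)
    start = 0
    for g, size in zip(GROUPS, sizes):
        group[order[start : start + size]] = g
        start += size
    tab["group"] = group
    return HierarchyAxis(table=tab, source=axis.source, orientation=axis.orientation)


def best_overlap_mapping(labels_a, labels_b) -> dict:
    """Map each parcel of labeling A to the B-parcel sharing the most vertices.

    Negative B labels are treated as unlabeled; an A-parcel overlapping only
    unlabeled vertices maps to ``None``.  Overlap ties resolve to the smaller
    B id with a warning.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    mapping: dict = {}
    for pa in np.unique(a):
        sel = b[a == pa]
        sel = sel[sel >= 0]
        if sel.size == 0:
            mapping[pa] = None
            continue
        ids, counts = np.unique(sel, return_counts=True)
        winners = ids[counts == counts.max()]
        if len(winners) > 1:
            log.warning(
                "parcel %s overlaps %d B-parcels equally; taking smallest id", pa, len(winners)
            )
        mapping[pa] = winners.min()
    return mapping


def axis_correlation(scores_a: pd.Series, scores_b: pd.Series):
    """Pearson correlation between two parcel axes over shared parcels."""
    a = pd.Series(scores_a)
    b = pd.Series(scores_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared parcels")
    x, y = a.loc[shared].to_numpy(float), b.loc[shared].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("axis scores have zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
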
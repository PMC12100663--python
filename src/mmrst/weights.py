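"""Spatial and space-time neighborhood structures.

``SpatialWeights`` stores a symmetric binary contiguity graph (optionally
row-standardized).  Builders cover lattice rook/queen contiguity, GeoJSON
polygon contiguity, and edge-list CSV round-trips; transforms cover
higher-order (graph-distance) neighborhoods and row standardization.
``SpaceTimeNeighborhood`` extends a spatial graph across adjacent time
steps for space-time statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import LatticeGeometry

__all__ = [
    "SpatialWeights",
    "SpaceTimeNeighborhood",
    "rook_adjacency",
    "higher_order",
    "row_standardize",
    "space_time_neighbors",
    "read_edgelist",
    "write_edgelist",
    "geojson_contiguity",
]


class SpatialWeights:
    """Symmetric binary adjacency over an ordered set of unit ids.

    Optionally carries per-neighbor weights (e.g. after row
    standardization); the base structure is always the unweighted graph.
    """

    def __init__(
        self,
        ids: Sequence[str],
        neighbors: dict[int, np.ndarray],
        weights: dict[int, np.ndarray] | None = None,
    ) -> None:
        self.ids: tuple[str, ...] = tuple(str(i) for i in ids)
        n = len(self.ids)
        self.neighbors: dict[int, np.ndarray] = {}
        for i in range(n):
            nb = np.asarray(neighbors.get(i, ()), dtype=np.intp)
            nb = np.unique(nb)
            if np.any(nb == i):
                raise ValueError(f"self-link at unit index {i}")
            if nb.size and (nb.min() < 0 or nb.max() >= n):
                raise ValueError("neighbor index out of range")
            self.neighbors[i] = nb
        # symmetry check
        for i, nb in self.neighbors.items():
            for j in nb:
                if i not in self.neighbors[int(j)]:
                    raise ValueError(f"asymmetric adjacency: {i}~{j} but not {j}~{i}")
        self.weights = None
        if weights is not None:
            self.weights = {
                i: np.asarray(weights[i], dtype=float) for i in range(n)
            }
            for i in range(n):
                if self.weights[i].shape != self.neighbors[i].shape:
                    raise ValueError("weights misaligned with neighbors")

    # -- basic views -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([self.neighbors[i].size for i in range(self.n)])

    @property
    def isolates(self) -> tuple[str, ...]:
        return tuple(self.ids[i] for i in range(self.n) if self.neighbors[i].size == 0)

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def edge_pairs(self) -> list[tuple[int, int]]:
        return [
            (i, int(j))
            for i in range((self.n))
            for j in self.neighbors[i]
            if i < j
        ]

    def to_sparse(self, standardized: bool = False) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i in range(self.n):
            nb = self.neighbors[i]
            if nb.size == 0:
                continue
            rows.extend([i] * nb.size)
            cols.extend(nb.tolist())
            if standardized:
                w = self.weights[i] if self.weights is not None else np.full(
                    nb.size, 1.0 / nb.size
                )
                vals.extend(w.tolist())
            else:
                vals.extend([1.0] * nb.size)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def laplacian(self) -> sp.csr_matrix:
        a = self.to_sparse()
        return sp.diags(np.asarray(a.sum(axis=1)).ravel()) - a

    def connected_components(self) -> np.ndarray:
        """Component label per unit (isolates are singleton components)."""
        n_comp, labels = sp.csgraph.connected_components(
            self.to_sparse(), directed=False
        )
        return labels

    def subset(self, keep_ids: Sequence[str]) -> "SpatialWeights":
        """Restriction to ``keep_ids``; cross-boundary edges are severed."""
        keep_ids = [str(k) for k in keep_ids]
        pos = {u: i for i, u in enumerate(self.ids)}
        old = [pos[k] for k in keep_ids]
        remap = {o: i for i, o in enumerate(old)}
        neighbors = {
            i: np.array(
                [remap[int(j)] for j in self.neighbors[o] if int(j) in remap],
                dtype=np.intp,
            )
            for i, o in enumerate(old)
        }
        return SpatialWeights(keep_ids, neighbors)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_edge_pairs(
        cls, ids: Sequence[str], pairs: Iterable[tuple[str, str]]
    ) -> "SpatialWeights":
        pos = {str(u): i for i, u in enumerate(ids)}
        nb: dict[int, set[int]] = {i: set() for i in range(len(pos))}
        for a, b in pairs:
            ia, ib = pos[str(a)], pos[str(b)]
            if ia == ib:
                continue
            nb[ia].add(ib)
            nb[ib].add(ia)
        return cls(ids, {i: np.array(sorted(s), dtype=np.intp) for i, s in nb.items()})


@dataclass(frozen=True)
class SpaceTimeNeighborhood:
    """Self-inclusive space-time neighbor structure on a unit × time grid.

    The neighbors of bin ``(i, t)`` are ``(j, t')`` for every ``j`` in the
    spatial neighborhood of ``i`` (plus ``i`` itself) and every ``t'``
    within ``lag`` steps of ``t``, clipped at the series boundaries.
    """

    weights: SpatialWeights
    n_times: int
    lag: int

    def __post_init__(self) -> None:
        if self.n_times < 1:
            raise ValueError("n_times must be >= 1")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")

    def time_window(self, t: int) -> range:
        return range(max(0, t - self.lag), min(self.n_times, t + self.lag + 1))

    def neighbors(self, i: int, t: int) -> list[tuple[int, int]]:
        spatial = [i] + [int(j) for j in self.weights.neighbors[i]]
        return [(j, tt) for j in spatial for tt in self.time_window(t)]

    def counts(self) -> np.ndarray:
        """|N(i,t)| for every bin, shape (n_units, n_times)."""
        deg = self.weights.degrees + 1
        win = np.array([len(self.time_window(t)) for t in range(self.n_times)])
        return deg[:, None] * win[None, :]


# ---------------------------------------------------------------------------
# builders & transforms


def rook_adjacency(
    geometry: LatticeGeometry, queen: bool = False
) -> SpatialWeights:
    """Contiguity on a grid: shared edge (rook) or edge-or-corner (queen)."""
    ids = geometry.county_ids
    if not ids:
        raise ValueError("empty geometry")
    by_coord = {tuple(geometry.coords[c]): k for k, c in enumerate(ids)}
    steps = [(0, 1), (1, 0)]
    if queen:
        steps += [(1, 1), (1, -1)]
    pairs = []
    for (r, c), i in by_coord.items():
        for dr, dc in steps:
            j = by_coord.get((r + dr, c + dc))
            if j is not None:
                pairs.append((ids[i], ids[j]))
    return SpatialWeights.from_edge_pairs(ids, pairs)


def higher_order(
    weights: SpatialWeights, order: int, cumulative: bool = True
) -> SpatialWeights:
    """Neighbors within graph distance ≤ ``order`` (or exactly ``order``).

    ``cumulative=True`` matches the convention of "neighborhood level k":
    all units reachable in at most ``k`` steps are neighbors.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order == 1:
        return SpatialWeights(weights.ids, weights.neighbors)
    nb_out: dict[int, np.ndarray] = {}
    for src in range(weights.n):
        dist = {src: 0}
        frontier = [src]
        for d in range(1, order + 1):
            nxt = []
            for u in frontier:
                for v in weights.neighbors[u]:
                    v = int(v)
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        if cumulative:
            keep = [u for u, d in dist.items() if 1 <= d <= order]
        else:
            keep = [u for u, d in dist.items() if d == order]
        nb_out[src] = np.array(sorted(keep), dtype=np.intp)
    return SpatialWeights(weights.ids, nb_out)


def row_standardize(weights: SpatialWeights) -> SpatialWeights:
    """Equal weights summing to 1 per row; isolates keep empty rows."""
    w = {
        i: (
            np.full(weights.neighbors[i].size, 1.0 / weights.neighbors[i].size)
            if weights.neighbors[i].size
            else np.empty(0)
        )
        for i in range(weights.n)
    }
    return SpatialWeights(weights.ids, weights.neighbors, w)


def space_time_neighbors(
    weights: SpatialWeights, n_times: int, lag: int = 1
) -> SpaceTimeNeighborhood:
    return SpaceTimeNeighborhood(weights, n_times, lag)


# ---------------------------------------------------------------------------
# IO


def write_edgelist(weights: SpatialWeights, path) -> None:
    pairs = weights.edge_pairs()
    pd.DataFrame(
        {
            "src": [weights.ids[i] for i, _ in pairs],
            "dst": [weights.ids[j] for _, j in pairs],
        }
    ).to_csv(path, index=False)


def read_edgelist(path, ids: Sequence[str] | None = None) -> SpatialWeights:
    """Edge-list CSV (columns src, dst).  ``ids`` fixes unit order and
    admits isolates not present in any edge."""
    df = pd.read_csv(path, dtype=str)
    if not {"src", "dst"} <= set(df.columns):
        raise ValueError("edge list needs columns src, dst")
    if ids is None:
        ids = sorted(set(df["src"]) | set(df["dst"]))
    return SpatialWeights.from_edge_pairs(ids, zip(df["src"], df["dst"]))


def geojson_contiguity(path, queen: bool = False) -> SpatialWeights:
    """Polygon contiguity from a GeoJSON FeatureCollection.

    Features must carry a ``county_id`` property.  Rook requires a shared
    boundary of positive length; queen accepts any touching geometry.
    """
    import json

    from shapely.geometry import shape
    from shapely.strtree import STRtree

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"]
    ids = [str(f["properties"]["county_id"]) for f in feats]
    geoms = [shape(f["geometry"]) for f in feats]
    tree = STRtree(geoms)
    pairs = []
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            other = geoms[j]
            if not g.touches(other) and not g.intersects(other):
                continue
            inter = g.boundary.intersection(other.boundary)
            if queen:
                if not inter.is_empty or g.touches(other):
                    pairs.append((ids[i], ids[j]))
            else:
                if inter.length > 0:
                    pairs.append((ids[i], ids[j]))
    return SpatialWeights.from_edge_pairs(ids, pairs)
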
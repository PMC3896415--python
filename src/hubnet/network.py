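"""Per-subject connectivity network construction.

Edges are Pearson correlations between regional time series, Fisher
r-to-z transformed, with the absolute z value as the edge weight.  Networks
are thresholded in two stages: a *local* threshold retains a maximum-weight
spanning tree ("backbone") so the graph can never fragment into isolated
islands, then a *global* threshold adds the strongest remaining edges until
a target density is reached.  Sweeping the density from 1% to 40% in 1%
steps yields a nested family of networks sharing one backbone; each can be
analysed as a binary or weighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .conditioning import RegionalTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "Edge",
    "DEFAULT_DENSITIES",
    "correlation_matrix",
    "fisher_z",
    "connectivity_from_timeseries",
    "backbone_mst",
    "backbone_per_node_strongest",
    "apply_global_threshold",
    "density_sweep",
    "binarize",
    "target_edge_count",
]

Edge = tuple[int, int]  # always stored with i < j

#: The full density grid: 1% to 40% at 1% increments.
DEFAULT_DENSITIES: tuple[float, ...] = tuple(np.round(np.arange(1, 41) / 100.0, 2))

R_CLIP = 1.0 - 1e-6  # clip correlations before atanh so weights stay finite


@dataclass
class ConnectivityMatrix:
    """Symmetric region × region matrix of |Fisher z| edge weights.

    The diagonal is structurally zero and never read as a weight.
    """

    subject_id: str
    weights: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.region_labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if off.size and off.min() < 0:
            raise ValueError("edge weights must be non-negative")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def edge_weight(self, a: int, b: int) -> float:
        if a == b:
            raise ValueError("self-weights are undefined")
        return float(self.weights[a, b])


@dataclass
class ThresholdedNetwork:
    """A subject's network at one density: backbone plus retained edges."""

    subject_id: str
    density: float
    n_regions: int
    edges: frozenset[Edge]
    backbone: frozenset[Edge]
    mode: str = "weighted"  # "weighted" or "binary"
    weights_retained: dict[Edge, float] | None = None
    sub_minimum_density: bool = False  # density target below backbone size

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "binary"):
            raise ValueError("mode must be 'weighted' or 'binary'")
        if not self.backbone <= self.edges:
            raise ValueError("backbone must be a subset of the edge set")
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < j < self.n_regions):
                raise ValueError(f"edge {(i, j)} not in canonical (i < j) range")
        if self.mode == "weighted" and self.weights_retained is not None:
            if set(self.weights_retained) != set(self.edges):
                raise ValueError("weights_retained keys must equal the edge set")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense adjacency matrix (binary 0/1 or weighted)."""
        a = np.zeros((self.n_regions, self.n_regions))
        for e in self.edges:
            v = 1.0 if self.mode == "binary" or self.weights_retained is None else self.weights_retained[e]
            a[e[0], e[1]] = a[e[1], e[0]] = v
        return a

    def is_connected(self) -> bool:
        parent = list(range(self.n_regions))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        n_comp = self.n_regions
        for i, j in self.edges:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                n_comp -= 1
        return n_comp == 1


def correlation_matrix(ts: RegionalTimeSeries) -> np.ndarray:
    """Pearson correlation between every pair of regional mean time series."""
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        dead = [ts.region_labels[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance region(s): {', '.join(dead)}")
    r = np.corrcoef(ts.data, rowvar=False)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def fisher_z(
    r_matrix: np.ndarray,
    region_labels: Sequence[str],
    subject_id: str = "",
) -> ConnectivityMatrix:
    """|atanh(r)| edge weights; r is clipped at ±(1 − 1e−6) to stay finite.

    The absolute value makes weight(r) = weight(−r): strongly anticorrelated
    pairs count as strong edges.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.abs(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        subject_id=subject_id, weights=(z + z.T) / 2.0, region_labels=list(region_labels)
    )


def connectivity_from_timeseries(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Convenience: Pearson correlations → |Fisher z| weights."""
    return fisher_z(correlation_matrix(ts), ts.region_labels, ts.subject_id)


def _sorted_edges(weights: np.ndarray) -> list[Edge]:
    """All i<j edges sorted by weight descending, ties lexicographic (i, j)."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return list(zip(iu[order].tolist(), ju[order].tolist()))


def backbone_mst(cm: ConnectivityMatrix) -> frozenset[Edge]:
    """Maximum-weight spanning tree over the |z| weights (Kruskal).

    Guarantees a connected, acyclic backbone of n − 1 edges touching every
    region.  Ties are broken lexicographically on (i, j), so the result is
    deterministic across runs and platforms.
    """
    n = cm.n_regions
    if n < 2:
        raise ValueError("need at least two regions")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[Edge] = []
    for i, j in _sorted_edges(cm.weights):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j))
            if len(tree) == n - 1:
                break
    return frozenset(tree)


def backbone_per_node_strongest(cm: ConnectivityMatrix) -> frozenset[Edge]:
    """Variant local threshold: keep each node's single strongest edge.

    This is the literal per-node reading of local thresholding; unlike the
    spanning tree it does not guarantee a connected backbone and yields
    between n/2 and n − 1 edges.  Provided for comparison only.
    """
    w = cm.weights.copy()
    np.fill_diagonal(w, -np.inf)
    best = np.argmax(w, axis=1)
    return frozenset(
        (min(i, int(j)), max(i, int(j))) for i, j in enumerate(best)
    )


def target_edge_count(density: float, n_regions: int) -> int:
    """round(density × n(n−1)/2), rounding half away from zero."""
    m = n_regions * (n_regions - 1) / 2.0
    return int(np.floor(density * m + 0.5))


def _check_density(density: float) -> None:
    if not 0 < density <= 0.40:
        raise ValueError(f"density must lie in (0, 0.40], got {density}")


def apply_global_threshold(
    cm: ConnectivityMatrix,
    backbone: frozenset[Edge],
    density: float,
    _sorted_nonbackbone: list[Edge] | None = None,
) -> ThresholdedNetwork:
    """Grow the backbone with the strongest remaining edges to a target density.

    The target edge count is round(density × n(n−1)/2).  If the target falls
    below the backbone size (very sparse networks on many regions), the
    backbone is returned unchanged and flagged ``sub_minimum_density`` rather
    than disconnecting the graph.
    """
    _check_density(density)
    n = cm.n_regions
    target = target_edge_count(density, n)
    if _sorted_nonbackbone is None:
        _sorted_nonbackbone = [e for e in _sorted_edges(cm.weights) if e not in backbone]
    n_extra = target - len(backbone)
    if n_extra < 0:
        edges = frozenset(backbone)
        flagged = True
    else:
        edges = frozenset(backbone) | frozenset(_sorted_nonbackbone[:n_extra])
        flagged = False
    return ThresholdedNetwork(
        subject_id=cm.subject_id,
        density=density,
        n_regions=n,
        edges=edges,
        backbone=frozenset(backbone),
        mode="weighted",
        weights_retained={e: cm.edge_weight(*e) for e in edges},
        sub_minimum_density=flagged,
    )


def density_sweep(
    cm: ConnectivityMatrix,
    densities: Sequence[float] = DEFAULT_DENSITIES,
    backbone: frozenset[Edge] | None = None,
) -> list[ThresholdedNetwork]:
    """One thresholded network per density, sharing a single backbone.

    Densities must be strictly increasing; the resulting edge sets are nested
    (the network at a lower density is a subgraph of every denser one).
    """
    densities = list(densities)
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("densities must be strictly increasing")
    for d in densities:
        _check_density(d)
    if backbone is None:
        backbone = backbone_mst(cm)
    nonbackbone = [e for e in _sorted_edges(cm.weights) if e not in backbone]
    return [
        apply_global_threshold(cm, backbone, d, _sorted_nonbackbone=nonbackbone)
        for d in densities
    ]


def binarize(net: ThresholdedNetwork) -> ThresholdedNetwork:
    """Same edge set with every retained weight treated as 1."""
    return replace(net, mode="binary", weights_retained=None)
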
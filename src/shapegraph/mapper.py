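"""The four Mapper stages: lens filtering, cover, partial clustering, linking.

Mapper compresses a point cloud into a *shape graph*.  A low-dimensional lens
projection slices the data into overlapping bins (a cover parameterized by
resolution R and gain G), each bin is clustered in the **original**
high-dimensional space, and clusters sharing samples are linked into a graph.

Gain convention
---------------
Adjacent cover intervals overlap by the fraction ``(G - 1) / G`` of their
width: G = 3 gives 66.7% overlap, G = 5 gives 80%.  With R intervals per
dimension over a range ``range``, each interval has width
``w = G * range / (R - 1 + G)`` and consecutive intervals start ``w / G``
apart, so the union spans the range exactly and every interior point lies in
up to G intervals per dimension.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .matrix import DataMatrix, as_sequence

__all__ = [
    "LensConfig",
    "Lens",
    "apply_lens",
    "Cover",
    "build_cover",
    "BinAssignment",
    "assign_bins",
    "ClustererConfig",
    "cluster_bin",
    "ShapeGraph",
    "Node",
    "link_clusters",
    "MapperConfig",
    "run_mapper",
    "save_graph_json",
    "load_graph_json",
]


# ---------------------------------------------------------------------------
# Stage 1: lens / filter
# ---------------------------------------------------------------------------

@dataclass
class LensConfig:
    """How to project samples to lens coordinates.

    method
        ``"identity"`` selects raw feature columns (``dims``); ``"pca"`` and
        ``"tsne"`` use scikit-learn with ``n_components`` output dimensions;
        ``"custom"`` calls ``method_params["function"](values) -> (n, d)``.
    dims
        Column indices for the identity lens.
    n_components
        Output dimensionality d for pca/tsne/custom.
    seed
        Random seed; mandatory for stochastic lenses (t-SNE) and recorded in
        provenance so runs are reproducible.
    method_params
        Extra keyword arguments forwarded to the scikit-learn estimator
        (e.g., ``perplexity`` for t-SNE).
    """

    method: str = "identity"
    dims: Sequence[int] = (0, 1)
    n_components: int = 2
    seed: int = 0
    method_params: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return len(self.dims) if self.method == "identity" else int(self.n_components)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "dims": list(self.dims),
            "n_components": int(self.n_components),
            "seed": int(self.seed),
            "method_params": {
                k: v for k, v in self.method_params.items() if not callable(v)
            },
        }


@dataclass
class Lens:
    """n_samples x d lens coordinates plus the config that produced them."""

    coords: np.ndarray
    config: LensConfig

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("lens coordinates must be 2-D")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("lens produced non-finite coordinates")

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def apply_lens(data: DataMatrix, config: LensConfig) -> Lens:
    """Project a data matrix to lens coordinates (Mapper stage 1).

    The lens only slices the data; later clustering happens in the original
    space, so lossy projections are acceptable here.
    """
    X = data.values
    if config.d < 1:
        raise ValueError("lens dimensionality must be >= 1")
    if config.method == "identity":
        dims = list(config.dims)
        if any(j < 0 or j >= data.n_features for j in dims):
            raise ValueError(f"identity lens dims {dims} outside feature range")
        coords = X[:, dims]
    elif config.method == "pca":
        from sklearn.decomposition import PCA

        k = min(data.n_samples, data.n_features)
        if config.n_components > k:
            raise ValueError(f"pca lens: {config.n_components} components infeasible for shape {X.shape}")
        pca = PCA(
            n_components=config.n_components,
            svd_solver="full",
            random_state=config.seed,
            **config.method_params,
        )
        coords = pca.fit_transform(X)
    elif config.method == "tsne":
        from sklearn.manifold import TSNE

        params = {"perplexity": min(30.0, max(2.0, (data.n_samples - 1) / 3.0))}
        params.update(config.method_params)
        tsne = TSNE(
            n_components=config.n_components,
            random_state=config.seed,
            init="pca",
            **params,
        )
        coords = tsne.fit_transform(X)
    elif config.method == "custom":
        fn: Callable = config.method_params.get("function")
        if fn is None:
            raise ValueError("custom lens requires method_params['function']")
        coords = np.asarray(fn(X), dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
    else:
        raise ValueError(f"unknown lens method {config.method!r}")
    if coords.shape[0] != data.n_samples:
        raise ValueError("lens output row count does not match the data")
    return Lens(np.asarray(coords, dtype=float), config)


# ---------------------------------------------------------------------------
# Stage 2: cover and bin assignment
# ---------------------------------------------------------------------------

@dataclass
class Cover:
    """Per-dimension overlapping intervals with resolution R and gain G.

    ``intervals[k]`` is the ordered list of ``(lo, hi)`` pairs for lens
    dimension k.  All intervals in a dimension share one width; adjacent
    intervals intersect on the fraction ``(G-1)/G`` of that width.
    """

    intervals: list[list[tuple[float, float]]]
    resolution: list[int]
    gain: list[int]

    @property
    def d(self) -> int:
        return len(self.intervals)

    def overlap_fraction(self, dim: int = 0) -> float:
        """Measured intersection length of adjacent intervals / interval width."""
        ivs = self.intervals[dim]
        if len(ivs) < 2:
            return 0.0
        (lo0, hi0), (lo1, hi1) = ivs[0], ivs[1]
        width = hi0 - lo0
        if width == 0:
            return 0.0
        return max(0.0, min(hi0, hi1) - max(lo0, lo1)) / width


def build_cover(lens: Lens, resolution, gain) -> Cover:
    """Construct the overlapping interval cover of the lens range (stage 2).

    ``resolution`` and ``gain`` may be scalars (broadcast over dimensions) or
    per-dimension sequences.  A zero-range dimension (all lens values equal)
    degenerates to a single zero-width interval, with a warning.
    """
    d = lens.d
    Rs = [int(r) for r in as_sequence(resolution, d, "resolution")]
    Gs = [int(g) for g in as_sequence(gain, d, "gain")]
    if any(r < 1 for r in Rs):
        raise ValueError("resolution must be >= 1 in every dimension")
    if any(g < 1 for g in Gs):
        raise ValueError("gain must be >= 1 in every dimension")
    intervals: list[list[tuple[float, float]]] = []
    for k in range(d):
        lo = float(lens.coords[:, k].min())
        hi = float(lens.coords[:, k].max())
        R, G = Rs[k], Gs[k]
        rng = hi - lo
        if rng == 0.0:
            warnings.warn(
                f"lens dimension {k} has zero range; using one degenerate interval",
                RuntimeWarning,
                stacklevel=2,
            )
            intervals.append([(lo, hi)])
            continue
        if R == 1:
            intervals.append([(lo, hi)])
            continue
        w = G * rng / (R - 1 + G)
        ivs = [(lo + i * w / G, lo + i * w / G + w) for i in range(R)]
        # guard against the last endpoint falling short of the max by rounding
        last_lo, last_hi = ivs[-1]
        ivs[-1] = (last_lo, max(last_hi, hi))
        intervals.append(ivs)
    return Cover(intervals, Rs, Gs)


@dataclass
class BinAssignment:
    """Map from a d-dimensional interval-index tuple to member sample indices.

    Only non-empty bins are stored.  A sample belongs to a bin iff every lens
    coordinate lies inside the corresponding closed interval, so boundary
    points join both neighboring intervals.
    """

    bins: dict[tuple[int, ...], np.ndarray]


def assign_bins(lens: Lens, cover: Cover) -> BinAssignment:
    """Bin samples by the Cartesian product of per-dimension intervals."""
    if cover.d != lens.d:
        raise ValueError(f"cover has {cover.d} dimensions, lens has {lens.d}")
    n = lens.coords.shape[0]
    # per-dimension membership lists
    memberships: list[list[list[int]]] = []
    for k in range(lens.d):
        ivs = cover.intervals[k]
        lo = np.array([a for a, _ in ivs])
        hi = np.array([b for _, b in ivs])
        x = lens.coords[:, k][:, None]
        inside = (x >= lo[None, :]) & (x <= hi[None, :])  # closed on both ends
        memberships.append([list(np.flatnonzero(row)) for row in inside])
    bins: dict[tuple[int, ...], list[int]] = {}
    for i in range(n):
        per_dim = [memberships[k][i] for k in range(lens.d)]
        for tup in itertools.product(*per_dim):
            bins.setdefault(tup, []).append(i)
    return BinAssignment({t: np.asarray(m, dtype=int) for t, m in sorted(bins.items())})


# ---------------------------------------------------------------------------
# Stage 3: partial clustering within bins
# ---------------------------------------------------------------------------

@dataclass
class ClustererConfig:
    """Within-bin clusterer settings.

    The default method is single-linkage agglomerative clustering on
    original-space distances, cut at the first empty bin of a
    ``histogram_bins``-bin histogram of merge distances (if the histogram has
    no empty bin, the whole bin is one cluster).  This gap heuristic is
    deterministic and parameter-light; any callable taking
    ``(values, member_indices)`` and returning a list of index lists can be
    substituted via ``method="custom"`` + ``method_params["function"]``.
    """

    method: str = "single-linkage-gap"
    histogram_bins: int = 10
    metric: str = "euclidean"
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "histogram_bins": int(self.histogram_bins),
            "metric": self.metric,
        }


def cluster_bin(
    data: DataMatrix,
    bin_members: Sequence[int],
    config: ClustererConfig | None = None,
) -> list[list[int]]:
    """Partition one bin's members into clusters in the original space.

    Returns a list of disjoint, non-empty lists of sample indices whose union
    is ``bin_members``.  Singleton bins yield one singleton cluster.
    """
    config = config or ClustererConfig()
    members = [int(i) for i in bin_members]
    if len(members) == 0:
        raise ValueError("bin is empty")
    if config.method == "custom":
        fn = config.method_params.get("function")
        if fn is None:
            raise ValueError("custom clusterer requires method_params['function']")
        return [list(map(int, c)) for c in fn(data.values, members)]
    if config.method != "single-linkage-gap":
        raise ValueError(f"unknown clustering method {config.method!r}")
    if len(members) == 1:
        return [members]
    dists = pdist(data.values[members], metric=config.metric)
    if float(dists.max()) == 0.0:
        return [members]  # duplicated rows: all merge distances zero
    Z = linkage(dists, method="single")
    heights = Z[:, 2]
    counts, edges = np.histogram(heights, bins=config.histogram_bins)
    empty = np.flatnonzero(counts == 0)
    if len(empty) == 0:
        return [members]
    threshold = edges[empty[0]]
    flat = fcluster(Z, t=threshold, criterion="distance")
    out: dict[int, list[int]] = {}
    for m, lab in zip(members, flat):
        out.setdefault(int(lab), []).append(m)
    return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# Stage 4: linking clusters into the shape graph
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """One shape-graph node: a cluster of samples from one cover bin."""

    id: int
    bin: tuple[int, ...]
    members: tuple[int, ...]


@dataclass
class ShapeGraph:
    """Mapper output: nodes are clusters, edges link clusters sharing samples."""

    nodes: list[Node]
    edges: list[tuple[int, int]]
    n_samples: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node(self, node_id: int) -> Node:
        for nd in self.nodes:
            if nd.id == node_id:
                return nd
        raise KeyError(f"no node with id {node_id}")

    def neighbors(self, node_id: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == node_id:
                out.append(b)
            elif b == node_id:
                out.append(a)
        return sorted(out)

    def to_networkx(self):
        """Return the graph as a :class:`networkx.Graph` with member attributes."""
        import networkx as nx

        g = nx.Graph()
        for nd in self.nodes:
            g.add_node(nd.id, members=list(nd.members), bin=nd.bin)
        g.add_edges_from(self.edges)
        return g


def link_clusters(
    clusters: Sequence[tuple[tuple[int, ...], Sequence[int]]],
    n_samples: int,
    provenance: dict | None = None,
) -> ShapeGraph:
    """Build the nerve: one node per cluster, edges where member sets intersect.

    ``clusters`` is a sequence of ``(bin_index_tuple, member_indices)`` pairs.
    Edges are deduplicated, undirected, and never self-loops.  Overlapping
    bins are not checked explicitly: sharing a sample is the linking rule.
    """
    nodes = [
        Node(i, tuple(int(x) for x in b), tuple(sorted(int(m) for m in mem)))
        for i, (b, mem) in enumerate(clusters)
    ]
    if any(len(nd.members) == 0 for nd in nodes):
        raise ValueError("clusters must be non-empty")
    # incidence matrix: clusters x samples; shared membership -> edge
    C = len(nodes)
    edges: list[tuple[int, int]] = []
    if C > 1:
        M = np.zeros((C, n_samples), dtype=bool)
        for nd in nodes:
            M[nd.id, list(nd.members)] = True
        share = M @ M.T
        ii, jj = np.nonzero(np.triu(share, k=1))
        edges = [(int(a), int(b)) for a, b in zip(ii, jj)]
    return ShapeGraph(nodes, edges, int(n_samples), provenance or {})


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass
class MapperConfig:
    """Full Mapper run configuration (lens, cover, clusterer, seed)."""

    lens: LensConfig = field(default_factory=LensConfig)
    resolution: int | Sequence[int] = 10
    gain: int | Sequence[int] = 3
    clusterer: ClustererConfig = field(default_factory=ClustererConfig)

    def to_dict(self) -> dict:
        res = self.resolution
        gn = self.gain
        return {
            "lens": self.lens.to_dict(),
            "resolution": list(res) if isinstance(res, (list, tuple)) else int(res),
            "gain": list(gn) if isinstance(gn, (list, tuple)) else int(gn),
            "clusterer": self.clusterer.to_dict(),
            "seed": int(self.lens.seed),
        }


def run_mapper(data: DataMatrix, config: MapperConfig) -> ShapeGraph:
    """Run all four Mapper stages and return the shape graph.

    Deterministic given the config (including the lens seed); the resolved
    configuration is recorded in ``graph.provenance``.
    """
    lens = apply_lens(data, config.lens)
    cover = build_cover(lens, config.resolution, config.gain)
    assignment = assign_bins(lens, cover)
    clusters: list[tuple[tuple[int, ...], list[int]]] = []
    for tup, members in assignment.bins.items():
        for c in cluster_bin(data, members, config.clusterer):
            clusters.append((tup, c))
    return link_clusters(clusters, data.n_samples, provenance=config.to_dict())


# ---------------------------------------------------------------------------
# Serialization (documented JSON interchange format, schema version 1)
# ---------------------------------------------------------------------------

def save_graph_json(graph: ShapeGraph, path: str | Path) -> None:
    """Write a shape graph as JSON: nodes [{id, members, bin}], links, provenance."""
    doc = {
        "schema": "shapegraph-graph/1",
        "n_samples": graph.n_samples,
        "nodes": [
            {"id": nd.id, "members": list(nd.members), "bin": list(nd.bin)}
            for nd in graph.nodes
        ],
        "links": [{"source": a, "target": b} for a, b in graph.edges],
        "provenance": graph.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_graph_json(path: str | Path) -> ShapeGraph:
    doc = json.loads(Path(path).read_text())
    nodes = [
        Node(int(n["id"]), tuple(n["bin"]), tuple(n["members"])) for n in doc["nodes"]
    ]
    edges = [(int(l["source"]), int(l["target"])) for l in doc["links"]]
    return ShapeGraph(nodes, edges, int(doc["n_samples"]), doc.get("provenance", {}))
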
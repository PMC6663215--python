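"""Shape-graph annotation and temporal connectivity analysis.

Projects a shape graph back to the sample (time-frame) domain: two frames are
*temporally connected* if they share a node or occupy nodes joined by an edge.
The resulting binary temporal connectivity matrix (TCM) and its normalized
degree track transitions between brain states at single-frame resolution;
conditioning connectivity on a categorical label track yields per-category
similarity matrices and connectivity time courses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mapper import ShapeGraph
from .matrix import LabelTrack

__all__ = [
    "NodeAnnotation",
    "annotate_nodes",
    "build_tcm",
    "degree_series",
    "CategorySimilarityMatrix",
    "category_similarity",
    "category_timecourse",
    "block_frame_sets",
    "save_tcm_csv",
    "save_series_csv",
]


@dataclass
class NodeAnnotation:
    """Per-node category composition.

    counts[node_id] maps category -> number of member frames with that label;
    proportions normalize counts by node size; dominant[node_id] is the most
    frequent category (lexicographically first on ties).
    """

    counts: dict[int, dict[str, int]]
    proportions: dict[int, dict[str, float]]
    dominant: dict[int, str]
    categories: list[str] = field(default_factory=list)


def annotate_nodes(graph: ShapeGraph, labels: LabelTrack) -> NodeAnnotation:
    """Count label categories over each node's member frames.

    Rendered downstream as pie-chart nodes: each node's slice proportions are
    the label mixture of the time frames it contains.
    """
    if len(labels) != graph.n_samples:
        raise ValueError(
            f"label track length {len(labels)} != n_samples {graph.n_samples}"
        )
    counts: dict[int, dict[str, int]] = {}
    proportions: dict[int, dict[str, float]] = {}
    dominant: dict[int, str] = {}
    for nd in graph.nodes:
        c = Counter(labels.labels[i] for i in nd.members)
        size = len(nd.members)
        counts[nd.id] = dict(sorted(c.items()))
        proportions[nd.id] = {k: v / size for k, v in sorted(c.items())}
        dominant[nd.id] = max(sorted(c), key=lambda k: c[k])
    return NodeAnnotation(counts, proportions, dominant, labels.categories)


def build_tcm(graph: ShapeGraph, n_samples: int | None = None) -> np.ndarray:
    """Temporal connectivity matrix: T x T binary, symmetric, unit diagonal.

    ``tcm[i, j] = 1`` iff frames i and j share a shape-graph node or occupy
    nodes joined by an edge.  The diagonal is forced to 1.
    """
    T = graph.n_samples if n_samples is None else int(n_samples)
    for nd in graph.nodes:
        if nd.members and max(nd.members) >= T:
            raise ValueError(f"node {nd.id} has member index >= n_samples {T}")
    C = graph.n_nodes
    tcm = np.zeros((T, T), dtype=np.int8)
    if C > 0:
        M = np.zeros((C, T), dtype=np.int8)
        for row, nd in enumerate(graph.nodes):
            M[row, list(nd.members)] = 1
        A = np.eye(C, dtype=np.int8)  # same-node connectivity
        for a, b in graph.edges:
            A[a, b] = 1
            A[b, a] = 1
        tcm = ((M.T @ A.astype(np.int64) @ M) > 0).astype(np.int8)
    np.fill_diagonal(tcm, 1)
    return tcm


def degree_series(tcm: np.ndarray) -> np.ndarray:
    """Normalized degree per frame: off-diagonal nonzeros in each row / (T-1).

    Values lie in [0, 1]; a single-frame matrix yields 0.  Dips in this
    series flag transition frames whose activity pattern resembles few other
    frames.
    """
    tcm = np.asarray(tcm)
    T = tcm.shape[0]
    if T <= 1:
        return np.zeros(T)
    off = (tcm != 0).sum(axis=1) - (np.diag(tcm) != 0).astype(int)
    return off / (T - 1)


@dataclass
class CategorySimilarityMatrix:
    """K x K mean temporal connectivity between (and within) label categories.

    ``matrix[a, b]`` is the mean of TCM entries over frame pairs (i, j) with
    label(i) = category a, label(j) = category b; same-category entries
    exclude i = j so the forced unit diagonal cannot inflate them.  Entries
    for categories with fewer than two frames are NaN and flagged in
    ``undefined``.
    """

    matrix: np.ndarray
    categories: list[str]
    undefined: list[str] = field(default_factory=list)

    def diagonal_mean(self) -> float:
        return float(np.nanmean(np.diag(self.matrix)))

    def offdiagonal_mean(self) -> float:
        K = len(self.categories)
        mask = ~np.eye(K, dtype=bool)
        return float(np.nanmean(self.matrix[mask]))


def category_similarity(
    tcm: np.ndarray,
    labels: LabelTrack,
    exclude_rest: bool = False,
) -> CategorySimilarityMatrix:
    """Mean TCM entry per ordered category pair (symmetric, in [0, 1])."""
    tcm = np.asarray(tcm, dtype=float)
    T = tcm.shape[0]
    if len(labels) != T:
        raise ValueError(f"label track length {len(labels)} != TCM size {T}")
    cats = labels.categories
    if exclude_rest:
        cats = [c for c in cats if c != labels.rest_label]
    K = len(cats)
    sim = np.full((K, K), np.nan)
    idx = {c: labels.indices_of(c) for c in cats}
    undefined = []
    for a, ca in enumerate(cats):
        for b, cb in enumerate(cats):
            ia, ib = idx[ca], idx[cb]
            block = tcm[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    undefined.append(ca)
                    continue
                total = block.sum() - np.trace(block)
                sim[a, b] = total / (len(ia) * (len(ia) - 1))
            else:
                sim[a, b] = block.mean()
    return CategorySimilarityMatrix(sim, cats, undefined)


def category_timecourse(tcm: np.ndarray, labels: LabelTrack) -> pd.DataFrame:
    """Per-category mean connectivity of every frame to that category's frames.

    Returns a T x K DataFrame: column c at frame t is the mean of
    ``tcm[t, j]`` over frames j labeled c, excluding j = t.  Rising and
    falling flanks of these series mark block onsets and offsets.
    """
    tcm = np.asarray(tcm, dtype=float)
    T = tcm.shape[0]
    if len(labels) != T:
        raise ValueError(f"label track length {len(labels)} != TCM size {T}")
    out = {}
    for c in labels.categories:
        j = labels.indices_of(c)
        if len(j) == 0:
            raise ValueError(f"category {c!r} has no frames")
        sums = tcm[:, j].sum(axis=1)
        counts = np.full(T, len(j), dtype=float)
        member = np.zeros(T, dtype=bool)
        member[j] = True
        sums[member] -= np.diag(tcm)[member]  # exclude the frame itself
        counts[member] -= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            series = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        out[c] = series
    return pd.DataFrame(out, index=pd.RangeIndex(T, name="frame"))


def block_frame_sets(labels: LabelTrack) -> tuple[np.ndarray, np.ndarray]:
    """Split non-rest frames into block-interior and block-boundary sets.

    A *block* is a maximal run of identical non-rest labels.  Its first and
    last frames are boundary (onset/offset) frames; the rest are interior.
    Returns ``(interior_indices, boundary_indices)``.
    """
    interior: list[int] = []
    boundary: list[int] = []
    T = len(labels)
    t = 0
    while t < T:
        if labels.labels[t] == labels.rest_label:
            t += 1
            continue
        start = t
        while t < T and labels.labels[t] == labels.labels[start]:
            t += 1
        boundary.extend({start, t - 1})
        interior.extend(range(start + 1, t - 1))
    return np.asarray(interior, dtype=int), np.asarray(boundary, dtype=int)


def save_tcm_csv(tcm: np.ndarray, path: str | Path) -> None:
    """Write the TCM as a plain delimited integer matrix (no header)."""
    np.savetxt(path, np.asarray(tcm, dtype=int), fmt="%d", delimiter=",")


def save_series_csv(series: np.ndarray | pd.DataFrame, path: str | Path) -> None:
    """Write a degree series or per-category time courses as tidy CSV."""
    if isinstance(series, pd.DataFrame):
        tidy = series.reset_index().melt(
            id_vars="frame", var_name="category", value_name="value"
        )
    else:
        tidy = pd.DataFrame(
            {"frame": np.arange(len(series)), "value": np.asarray(series)}
        )
    tidy.to_csv(path, index=False)
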
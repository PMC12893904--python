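"""Tissue region identification by graph heat-kernel smoothing.

Large-length-scale ("region") expression patterns are isolated by low-pass
filtering the cell x gene matrix over a spatial Delaunay triangulation of the
cell positions. The filter is the heat kernel exp(-t * L_rw) with default
diffusion time t = 10, where L_rw = I - D^-1 A is the random-walk normalised
graph Laplacian (so constant signals are preserved exactly and t is
independent of the degree scale). PCA on the smoothed matrix followed by
k-means yields categorical region labels; k-means (rather than a graph-based
clustering) avoids smoothing-induced spatial autocorrelation artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "SpatialGraph",
    "SmoothingConfig",
    "RegionLabels",
    "delaunay_adjacency",
    "heat_smooth",
    "region_call",
    "RegionModel",
    "RegionResults",
]


@dataclass
class SpatialGraph:
    """Undirected spatial neighbour graph from a Delaunay triangulation."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int array, i < j, unique
    adjacency: sparse.csr_matrix

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


@dataclass
class SmoothingConfig:
    t: float = 10.0
    laplacian: str = "random-walk"
    solver_tol: float = 1e-8

    def validate(self) -> None:
        if self.t < 0:
            raise ValueError("heat-kernel time t must be >= 0")
        if self.laplacian != "random-walk":
            raise ValueError("only the random-walk Laplacian is supported")


@dataclass
class RegionLabels:
    labels: pd.Series  # cell id -> region id, contiguous from 0
    k: int
    n_pcs: int
    seed: int
    metadata: dict


def delaunay_adjacency(
    points: np.ndarray, max_edge_length: float | None = None
) -> SpatialGraph:
    """Neighbour graph from the 2-D Delaunay triangulation of cell positions.

    Edges longer than ``max_edge_length`` (um) are pruned when given; by
    default no pruning. Duplicate coordinates and all-collinear inputs raise
    (callers may jitter duplicates).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 3:
        raise ValueError("need >= 3 points for a triangulation")
    if len(np.unique(pts, axis=0)) != len(pts):
        raise ValueError("duplicate coordinates; jitter points before triangulating")
    try:
        tri = Delaunay(pts)
    except QhullError as e:  # all-collinear or otherwise degenerate
        raise ValueError(f"degenerate point configuration: {e}") from e

    s = tri.simplices
    e = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e.sort(axis=1)
    e = np.unique(e, axis=0)
    if max_edge_length is not None:
        keep = np.linalg.norm(pts[e[:, 0]] - pts[e[:, 1]], axis=1) <= max_edge_length
        e = e[keep]
    n = len(pts)
    adj = sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    adj = (adj + adj.T).tocsr()
    return SpatialGraph(n_nodes=n, edges=e, adjacency=adj)


def _component_kernel(adj: sparse.spmatrix, t: float) -> np.ndarray:
    """Dense exp(-t * L_rw) for one connected component via the symmetric form.

    L_rw = D^-1/2 L_sym D^1/2, so exp(-t L_rw) = D^-1/2 U exp(-t S) U^T D^1/2
    with L_sym = I - D^-1/2 A D^-1/2 = U S U^T.
    """
    a = np.asarray(adj.todense(), dtype=float)
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    l_sym = np.eye(len(a)) - inv_sqrt[:, None] * a * inv_sqrt[None, :]
    vals, vecs = eigh(l_sym)
    core = (vecs * np.exp(-t * vals)) @ vecs.T
    return inv_sqrt[:, None] * core * np.sqrt(d)[None, :]


def heat_smooth(
    X: np.ndarray, graph: SpatialGraph, config: SmoothingConfig | None = None
) -> np.ndarray:
    """Low-pass filter the cell x gene matrix: exp(-t * L_rw) @ X.

    Smoothing is applied per connected component; zero-degree (isolated)
    nodes are left unsmoothed with a warning. t = 0 returns the input
    unchanged.
    """
    config = config or SmoothingConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    if X.shape[0] != graph.n_nodes:
        raise ValueError(
            f"matrix has {X.shape[0]} rows but graph has {graph.n_nodes} nodes"
        )
    if config.t == 0:
        return X.copy()

    out = X.copy()
    deg = graph.degrees
    isolated = deg == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated node(s) left unsmoothed", stacklevel=2
        )
    n_comp, comp = connected_components(graph.adjacency, directed=False)
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if len(idx) == 1:
            continue  # isolated node: identity
        kernel = _component_kernel(graph.adjacency[np.ix_(idx, idx)], config.t)
        out[idx] = kernel @ X[idx]
    return out


def region_call(
    X_smoothed: np.ndarray,
    n_pcs: int,
    k: int,
    seed: int = 0,
    cell_ids: pd.Index | None = None,
) -> RegionLabels:
    """PCA (per-gene centred) then k-means on the top PCs; deterministic per seed."""
    X = np.asarray(X_smoothed, dtype=float)
    n_cells, n_genes = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_cells:
        raise ValueError("k exceeds the number of cells")
    n_pcs = min(n_pcs, n_cells, n_genes)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pcs)
    raw = km.labels_
    # Relabel so region ids are contiguous from 0 in order of first appearance.
    _, labels = np.unique(raw, return_inverse=True)
    order = {}
    remap = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        remap[i] = order[lab]
    if cell_ids is None:
        cell_ids = pd.RangeIndex(n_cells)
    return RegionLabels(
        labels=pd.Series(remap, index=cell_ids, name="region"),
        k=k,
        n_pcs=n_pcs,
        seed=seed,
        metadata={"inertia": float(km.inertia_)},
    )


class RegionModel:
    """Heat-kernel smoothing + PCA + k-means region model.

    Parameters
    ----------
    adata : AnnData with cell x gene values in .X and coordinates in
        obs["x"], obs["y"] (alternatively pass ``points`` explicitly).
    config : SmoothingConfig (t defaults to 10).
    """

    def __init__(self, adata, config: SmoothingConfig | None = None, points=None):
        self.adata = adata
        self.config = config or SmoothingConfig()
        if points is None:
            points = adata.obs[["x", "y"]].to_numpy(float)
        self.points = np.asarray(points, dtype=float)
        self.graph = delaunay_adjacency(self.points)

    def fit(self, k: int, n_pcs: int = 20, seed: int = 0) -> "RegionResults":
        X = self.adata.X
        X = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)
        smoothed = heat_smooth(X, self.graph, self.config)
        labels = region_call(
            smoothed, n_pcs=n_pcs, k=k, seed=seed, cell_ids=self.adata.obs_names
        )
        labels.metadata.update(
            {"t": self.config.t, "laplacian": self.config.laplacian, "input": "adata.X"}
        )
        return RegionResults(self, smoothed, labels)


class RegionResults:
    def __init__(self, model: RegionModel, smoothed: np.ndarray, regions: RegionLabels):
        self.model = model
        self.smoothed = smoothed
        self.regions = regions

    @property
    def labels(self) -> pd.Series:
        return self.regions.labels

    def summary(self) -> str:
        counts = self.labels.value_counts().sort_index()
        lines = [
            f"Region model: t={self.model.config.t}, k={self.regions.k}, "
            f"n_pcs={self.regions.n_pcs}, seed={self.regions.seed}",
            "cells per region: " + ", ".join(f"{i}: {c}" for i, c in counts.items()),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(
            self.model.points[:, 0],
            self.model.points[:, 1],
            c=self.labels.to_numpy(),
            s=8,
            cmap="tab10",
        )
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        return ax
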
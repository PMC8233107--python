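"""Simplicial feature vectors and the three simplicial distances.

Each retained time point becomes a StatePoint carrying three views of the
instantaneous brain state: the node topography (|CWT| amplitudes across
retained scales), the edge geometry (upper-triangle graph weights), and the
per-region weighted degree (strength). Distances: Euclidean between node
vectors, weighted Jaccard between edge vectors, weighted Jaccard between
strength vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coherence import TVFCSeries

SIMPLICIAL_METRICS = ("node", "edge", "strength")
TOPOLOGICAL_METRICS = ("H0", "H1", "H2")
ALL_METRICS = SIMPLICIAL_METRICS + TOPOLOGICAL_METRICS


@dataclass
class StatePoint:
    """One time point's simplicial feature vectors plus metadata."""

    volunteer: str
    time_index: int
    condition: str
    performance: float | None
    node_vector: np.ndarray      # region-major |W| over retained scales
    edge_vector: np.ndarray      # upper triangle, weight convention applied
    strength_vector: np.ndarray  # per-region weighted degree

    def __post_init__(self) -> None:
        for name in ("node_vector", "edge_vector", "strength_vector"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, v)


@dataclass
class StateDistanceMatrix:
    """Pairwise distances between state points under one named metric."""

    metric_name: str
    D: np.ndarray
    points: pd.DataFrame  # one row of metadata per state point, in row order

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")
        if len(self.points) != self.D.shape[0]:
            raise ValueError("metadata rows must match matrix size")

    @property
    def n(self) -> int:
        return self.D.shape[0]


def graph_weights(graph: np.ndarray, weight_mode: str = "coherence") -> np.ndarray:
    """Convert a coherence-distance graph to the configured weight convention.

    'coherence' uses 1 - distance (shared-connectivity intensity, the
    default); 'distance' uses the stored coherence distances directly.
    """
    if weight_mode == "coherence":
        w = 1.0 - graph
        if w.ndim == 2:
            np.fill_diagonal(w, 0.0)
        return w
    if weight_mode == "distance":
        return graph.copy()
    raise ValueError("weight_mode must be 'coherence' or 'distance'")


def strength_vector(graph: np.ndarray, weight_mode: str = "coherence") -> np.ndarray:
    """Per-region weighted degree of a symmetric zero-diagonal graph."""
    graph = np.asarray(graph, dtype=float)
    if graph.ndim != 2 or graph.shape[0] != graph.shape[1]:
        raise ValueError("graph must be square")
    if not np.allclose(graph, graph.T, atol=1e-9):
        raise ValueError("graph must be symmetric")
    w = graph_weights(graph, weight_mode)
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=1)


def extract_state_points(tvfc: TVFCSeries,
                         weight_mode: str = "coherence") -> list[StatePoint]:
    """Build a StatePoint per retained time point of one volunteer's TVFC."""
    if tvfc.spectrogram is None:
        raise ValueError("TVFCSeries must retain its spectrogram for node vectors")
    coeffs = np.abs(tvfc.spectrogram.coeffs)  # (R, S_kept, T_kept)
    R = tvfc.n_regions
    iu, ju = np.triu_indices(R, k=1)
    pts: list[StatePoint] = []
    for k in range(tvfc.n_points):
        g = tvfc.graphs[k]
        w = graph_weights(g, weight_mode)
        row = tvfc.point_meta.iloc[k]
        pts.append(StatePoint(
            volunteer=row["volunteer"],
            time_index=int(row["time_index"]),
            condition=row["condition"],
            performance=None if pd.isna(row["performance"]) else float(row["performance"]),
            node_vector=coeffs[:, :, k].reshape(-1),
            edge_vector=w[iu, ju],
            strength_vector=strength_vector(g, weight_mode),
        ))
    return pts


def weighted_jaccard(w1: np.ndarray, w2: np.ndarray) -> float:
    """Weighted Jaccard overlap distance 1 - sum(min)/sum(max) in [0, 1].

    Two all-zero vectors are identically empty and get distance 0.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError("vectors must share length")
    if (w1 < 0).any() or (w2 < 0).any():
        raise ValueError("weighted Jaccard requires nonnegative weights")
    mx = np.maximum(w1, w2).sum()
    if mx <= 0:
        return 0.0
    return float(1.0 - np.minimum(w1, w2).sum() / mx)


def node_distance(p1: StatePoint | np.ndarray, p2: StatePoint | np.ndarray) -> float:
    """Euclidean distance between node-topography vectors."""
    v1 = p1.node_vector if isinstance(p1, StatePoint) else np.asarray(p1, float)
    v2 = p2.node_vector if isinstance(p2, StatePoint) else np.asarray(p2, float)
    if v1.shape != v2.shape:
        raise ValueError("node vectors must share length")
    return float(np.linalg.norm(v1 - v2))


def _vectors(points: Sequence[StatePoint], metric_name: str) -> np.ndarray:
    attr = {"node": "node_vector", "edge": "edge_vector",
            "strength": "strength_vector"}[metric_name]
    return np.stack([getattr(p, attr) for p in points])


def _meta_frame(points: Sequence[StatePoint]) -> pd.DataFrame:
    return pd.DataFrame({
        "volunteer": [p.volunteer for p in points],
        "time_index": [p.time_index for p in points],
        "condition": [p.condition for p in points],
        "performance": [p.performance for p in points],
    })


def _jaccard_matrix(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """All-pairs weighted Jaccard distances between rows of V and rows of W."""
    out = np.empty((V.shape[0], W.shape[0]))
    for i, v in enumerate(V):
        mn = np.minimum(v[None, :], W).sum(axis=1)
        mx = np.maximum(v[None, :], W).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = 1.0 - np.divide(mn, mx, out=np.ones_like(mx), where=mx > 0)
        d[mx <= 0] = 0.0
        out[i] = d
    return out


def simplicial_cross_distances(points_a: Sequence[StatePoint],
                               points_b: Sequence[StatePoint],
                               metric_name: str) -> np.ndarray:
    """Rectangular distance block between two point sets (same metric)."""
    if metric_name not in SIMPLICIAL_METRICS:
        raise ValueError(f"unknown simplicial metric {metric_name!r}; "
                         f"choose from {SIMPLICIAL_METRICS}")
    A = _vectors(points_a, metric_name)
    B = _vectors(points_b, metric_name)
    if metric_name == "node":
        from scipy.spatial.distance import cdist
        return cdist(A, B)
    return _jaccard_matrix(A, B)


def pairwise_distances(points: Sequence, metric_name: str,
                       n_slices: int | None = None) -> StateDistanceMatrix:
    """Full symmetric distance matrix under one of the six metrics.

    Simplicial metrics take StatePoints; topological metrics (H0/H1/H2) take
    persistence diagrams paired with a metadata frame via
    :func:`brainstates.topology.diagram_distance_matrix`.
    """
    if metric_name not in ALL_METRICS:
        raise ValueError(
            f"unknown metric {metric_name!r}; the six metrics are {ALL_METRICS}"
        )
    if metric_name in TOPOLOGICAL_METRICS:
        from . import topology
        kwargs = {} if n_slices is None else {"n_slices": n_slices}
        return topology.diagram_distance_matrix(points, metric_name=metric_name,
                                                **kwargs)
    pts = list(points)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    D = simplicial_cross_distances(pts, pts, metric_name)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return StateDistanceMatrix(metric_name=metric_name, D=D,
                               points=_meta_frame(pts))
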
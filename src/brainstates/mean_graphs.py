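"""Mean performance graphs and secondary distance statistics.

For each task and performance valence (more vs. fewer correct responses than
the task's mean split), the element-wise mean of all qualifying TVFC graphs
forms a "mean performance graph". Distances between mean graphs — weighted
Jaccard between edge weights and sliced-Wasserstein between H0 persistence
diagrams — measure each metric's sensitivity to performance-driven state
differences; RMS/SD distances from a mean graph back to its component graphs
locate the mean within the cloud it summarises.

Distance computations reuse the metric and topology modules verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as bm
from . import topology


@dataclass
class MeanGraph:
    """Element-wise mean coherence-distance graph over component time points."""

    task: str
    valence: str                      # "high" | "low"
    graph: np.ndarray                 # (R, R) in [0, 1]
    component_ids: list[tuple]        # contributing (volunteer, time, draw) ids

    def __post_init__(self) -> None:
        g = np.asarray(self.graph, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("mean graph must be square")
        if not np.allclose(g, g.T, atol=1e-9):
            raise ValueError("mean graph must be symmetric")
        if not self.component_ids:
            raise ValueError("mean graph needs at least one component")
        self.graph = g


def build_mean_graph(graphs: Sequence[np.ndarray], component_ids: Sequence[tuple],
                     task: str = "", valence: str = "") -> MeanGraph:
    """Element-wise mean over component graphs; duplicates are allowed
    (a time point contributes once per bootstrap draw in which it qualifies)."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("cannot average an empty graph list")
    if len(graphs) != len(component_ids):
        raise ValueError("one component id per graph required")
    stack = np.stack([np.asarray(g, dtype=float) for g in graphs])
    return MeanGraph(task=task, valence=valence, graph=stack.mean(axis=0),
                     component_ids=list(component_ids))


def _edge_vector(graph: np.ndarray, weight_mode: str) -> np.ndarray:
    iu, ju = np.triu_indices(graph.shape[0], k=1)
    return bm.graph_weights(graph, weight_mode)[iu, ju]


def _h0_diagram(graph: np.ndarray) -> topology.PersistenceDiagram:
    filt = topology.Filtration(distance_matrix=graph, max_dim=0)
    return topology.vr_persistence(filt)[0]


def cross_valence_distances(means: Sequence[MeanGraph],
                            weight_mode: str = "coherence",
                            n_slices: int | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Edge-Jaccard and sliced-Wasserstein-H0 matrices over mean-graph pairs.

    Returns (jaccard matrix, SW-H0 matrix, flags) where ``flags`` marks
    cross-valence pairs within the same task.
    """
    means = list(means)
    if len(means) < 2:
        raise ValueError("need at least two mean graphs")
    names = [f"{m.task}/{m.valence}" for m in means]
    edges = [_edge_vector(m.graph, weight_mode) for m in means]
    dgms = [_h0_diagram(m.graph) for m in means]
    n = len(means)
    DJ = np.zeros((n, n))
    sw_kwargs = {} if n_slices is None else {"n_slices": n_slices}
    DW = topology.diagram_distance_matrix(dgms, **sw_kwargs).D
    flags = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            DJ[i, j] = DJ[j, i] = bm.weighted_jaccard(edges[i], edges[j])
            flags[i, j] = flags[j, i] = (
                means[i].task == means[j].task
                and means[i].valence != means[j].valence
            )
    return (pd.DataFrame(DJ, index=names, columns=names),
            pd.DataFrame(DW, index=names, columns=names),
            pd.DataFrame(flags, index=names, columns=names))


def rms_to_components(mean: MeanGraph, components: Sequence[np.ndarray],
                      metric: str = "edge",
                      weight_mode: str = "coherence",
                      n_slices: int | None = None) -> tuple[float, float]:
    """RMS and SD of the distance between a mean graph and each component.

    ``metric`` is 'edge' (weighted Jaccard) or 'H0' (sliced-Wasserstein).
    """
    components = list(components)
    if len(components) < 2:
        raise ValueError("need at least two components")
    if metric == "edge":
        mv = _edge_vector(mean.graph, weight_mode)
        dists = np.array([
            bm.weighted_jaccard(mv, _edge_vector(np.asarray(g), weight_mode))
            for g in components
        ])
    elif metric == "H0":
        md = _h0_diagram(mean.graph)
        sw_kwargs = {} if n_slices is None else {"n_slices": n_slices}
        dists = np.array([
            topology.sliced_wasserstein(md, _h0_diagram(np.asarray(g)), **sw_kwargs)
            for g in components
        ])
    else:
        raise ValueError(f"unknown metric {metric!r}; choose 'edge' or 'H0'")
    return float(np.sqrt(np.mean(dists ** 2))), float(np.std(dists))


def performance_mean_graphs(features, draw_results: Sequence,
                            weight_mode: str = "coherence") -> list[MeanGraph]:
    """Pool valenced cluster members across draws into mean performance graphs.

    ``draw_results`` are stats.DrawResult objects for one metric; a test point
    contributes once per draw in which it falls into a significantly
    high- (or low-) performance cluster for its task.
    """
    buckets: dict[tuple[str, str], list[tuple]] = {}
    for d, res in enumerate(draw_results):
        meta = res.test_meta
        a = res.test_assignments
        for task, pr in res.performance.items():
            for valence, clusters in (("high", pr.high_clusters),
                                      ("low", pr.low_clusters)):
                if not clusters:
                    continue
                sel = (meta["condition"].to_numpy() == task) & np.isin(a, clusters)
                for i in np.flatnonzero(sel):
                    row = meta.iloc[i]
                    buckets.setdefault((task, valence), []).append(
                        (row["volunteer"], int(row["time_index"]), d))
    out = []
    for (task, valence), ids in sorted(buckets.items()):
        graphs = []
        for vol, t, d in ids:
            m = features.meta[vol]
            pos = int(np.flatnonzero(m["time_index"].to_numpy() == t)[0])
            graphs.append(features.graphs[vol][pos])
        out.append(build_mean_graph(graphs, ids, task=task, valence=valence))
    return out
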
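"""Vietoris-Rips persistent homology of weighted graphs and the
sliced-Wasserstein distance between persistence diagrams.

A TVFC coherence-distance graph is filtered by edge length: K_r is the clique
complex of the graph restricted to edges strictly shorter than r. Homology
classes in dimension 0 (components), 1 (loops) and 2 (cavities) are tracked
across the filtration and summarised as (birth, death) pairs.

Dimension-0 persistence is exactly the single-linkage dendrogram of the
distance matrix (deaths = merge heights, all births at zero), and is computed
that way. Dimensions 1 and 2 use an in-package Z2 boundary-matrix reduction
with the clearing optimisation; columns are Python-int bitsets, which keeps
the symmetric-difference inner loop in C. Ties in filtration value are broken
by lexicographic simplex order so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import defaults
from .metrics import StateDistanceMatrix

NODE_GUARD = 400  # refuse VR dim>=2 above this size: C(n,4) columns blow up


@dataclass
class PersistenceDiagram:
    """Finite (birth, death) pairs in one homology dimension.

    Essential classes (never dying within the filtration) are counted but
    excluded from ``pairs``; the single essential H0 component is common to
    every diagram and carries no contrast between states.
    """

    dimension: int
    pairs: np.ndarray         # (m, 2), death > birth
    essential_count: int = 0

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        if self.pairs.size and not (self.pairs[:, 1] > self.pairs[:, 0]).all():
            raise ValueError("every death must exceed its birth")
        if self.dimension == 0 and self.pairs.size and self.pairs[:, 0].any():
            raise ValueError("H0 births must all be zero")

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


@dataclass
class Filtration:
    """A symmetric nonnegative zero-diagonal distance matrix to be filtered."""

    distance_matrix: np.ndarray
    max_radius: float | None = None   # None: run the filtration to the end
    max_dim: int = defaults.MAX_HOMOLOGY_DIM

    def __post_init__(self) -> None:
        D = np.asarray(self.distance_matrix, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(D)):
            raise ValueError("distance matrix contains NaN/inf")
        if (D < 0).any():
            raise ValueError("distance matrix contains negative entries")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(D)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        if not 0 <= self.max_dim <= defaults.MAX_HOMOLOGY_DIM:
            raise ValueError("max_dim must lie in {0, 1, 2}")
        self.distance_matrix = 0.5 * (D + D.T)


def h0_single_linkage(distance_matrix: np.ndarray) -> np.ndarray:
    """Ascending single-linkage merge heights: the H0 death times."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.shape[0] == 1:
        return np.empty(0)
    Z = linkage(squareform(D, checks=False), method="single")
    return np.sort(Z[:, 2])


def _sorted_simplices(D: np.ndarray, dim: int) -> tuple[list[tuple], np.ndarray]:
    """All dim-simplices with VR filtration values, sorted by (value, lex)."""
    n = D.shape[0]
    simplices = list(combinations(range(n), dim + 1))
    if dim == 0:
        vals = np.zeros(len(simplices))
    else:
        vals = np.array([
            max(D[a][b] for a, b in combinations(s, 2)) for s in simplices
        ])
    order = sorted(range(len(simplices)), key=lambda i: (vals[i], simplices[i]))
    return [simplices[i] for i in order], vals[np.asarray(order, dtype=int)]


def _reduce_dimension(cols: list[int],
                      cleared: set[int]) -> tuple[list[tuple[int, int]], set[int]]:
    """Left-to-right Z2 column reduction for one boundary-matrix dimension.

    ``cols[i]`` is the boundary of the i-th (filtration-ordered) simplex as a
    bitset over row ranks. Returns (pairs of (row, col) ranks, positive cols).
    """
    low_table: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    positive: set[int] = set()
    for j, b in enumerate(cols):
        if j in cleared:
            continue
        while b:
            low = b.bit_length() - 1
            other = low_table.get(low)
            if other is None:
                break
            b ^= other
        if b:
            low_table[b.bit_length() - 1] = b
            pairs.append((b.bit_length() - 1, j))
        else:
            positive.add(j)
    return pairs, positive


def vr_persistence(filtration: Filtration, force: bool = False) -> list[PersistenceDiagram]:
    """Persistence diagrams of the Vietoris-Rips filtration, dims 0..max_dim.

    H0 delegates to single-linkage (exact equivalence); higher dimensions run
    the boundary-matrix reduction. Strict sublevel semantics (edges enter at
    their length; equal-length simplices ordered lexicographically).
    """
    D = filtration.distance_matrix
    n = D.shape[0]
    if n < 1:
        raise ValueError("need at least one node")
    max_dim = filtration.max_dim
    if n > NODE_GUARD and max_dim >= 2 and not force:
        raise ValueError(
            f"{n} nodes with max_dim={max_dim} is combinatorially explosive; "
            "pass force=True to override"
        )
    max_r = filtration.max_radius

    # --- dimension 0 via single-linkage ---
    deaths = h0_single_linkage(D) if n > 1 else np.empty(0)
    if max_r is not None:
        essential0 = 1 + int((deaths > max_r).sum())
        deaths = deaths[deaths <= max_r]
    else:
        essential0 = 1
    finite = deaths[deaths > 0]
    diagrams = [PersistenceDiagram(
        dimension=0,
        pairs=np.column_stack([np.zeros(finite.size), finite]),
        essential_count=essential0,
    )]
    if max_dim == 0:
        return diagrams

    # --- dimensions >= 1 via reduction with clearing (top-down) ---
    by_dim: dict[int, tuple[list[tuple], np.ndarray]] = {}
    for d in range(1, max_dim + 2):
        simp, vals = _sorted_simplices(D, d)
        if max_r is not None:
            keep = vals <= max_r
            simp = [s for s, k in zip(simp, keep) if k]
            vals = vals[keep]
        by_dim[d] = (simp, vals)

    rank: dict[int, dict[tuple, int]] = {
        d: {s: i for i, s in enumerate(by_dim[d][0])} for d in range(1, max_dim + 2)
    }

    cleared: dict[int, set[int]] = {d: set() for d in range(1, max_dim + 2)}
    pair_lists: dict[int, list[tuple[int, int]]] = {}
    positive_sets: dict[int, set[int]] = {}
    paired_rows: dict[int, set[int]] = {d: set() for d in range(0, max_dim + 2)}

    for d in range(max_dim + 1, 0, -1):
        simp, _vals = by_dim[d]
        if d - 1 >= 1:
            facet_rank = rank[d - 1]
            cols = [
                sum(1 << facet_rank[f] for f in combinations(s, d))
                for s in simp
            ]
        else:
            cols = [ (1 << s[0]) | (1 << s[1]) for s in simp ]
        pairs, positive = _reduce_dimension(cols, cleared[d])
        pair_lists[d] = pairs
        positive_sets[d] = positive
        for row, _col in pairs:
            paired_rows[d - 1].add(row)
            if d - 1 >= 1:
                cleared[d - 1].add(row)

    for k in range(1, max_dim + 1):
        simp_k, vals_k = by_dim[k]
        simp_k1, vals_k1 = by_dim[k + 1]
        pts = []
        for row, col in pair_lists[k + 1]:
            birth = vals_k[row]
            death = vals_k1[col]
            if death > birth:
                pts.append((birth, death))
        # essential k-classes: positive k-columns never paired from above
        essential = sum(
            1 for j in positive_sets[k] if j not in paired_rows[k]
        )
        pts_arr = np.array(sorted(pts)) if pts else np.empty((0, 2))
        diagrams.append(PersistenceDiagram(dimension=k, pairs=pts_arr,
                                           essential_count=essential))
    return diagrams


def tvfc_diagrams(graphs: np.ndarray, max_dim: int = defaults.MAX_HOMOLOGY_DIM,
                  force: bool = False) -> list[list[PersistenceDiagram]]:
    """VR diagrams (dims 0..max_dim) for each graph in a TVFC stack."""
    return [
        vr_persistence(Filtration(distance_matrix=g, max_dim=max_dim), force=force)
        for g in graphs
    ]


def _slice_angles(n_slices: int) -> np.ndarray:
    """Fixed evenly spaced directions in [-pi/2, pi/2)."""
    return -np.pi / 2 + np.pi * np.arange(n_slices) / n_slices


def sliced_wasserstein(d1: PersistenceDiagram, d2: PersistenceDiagram,
                       n_slices: int = defaults.N_SLICES) -> float:
    """Sliced-Wasserstein distance between two persistence diagrams.

    Each diagram is augmented with the diagonal projections of the other's
    points; for each direction the augmented multisets are projected, sorted,
    and matched by rank at l1 cost; the result is the mean over slices.
    Deterministic: slices are fixed evenly spaced angles, not random draws.
    """
    if d1.dimension != d2.dimension:
        raise ValueError(
            f"dimension mismatch: {d1.dimension} vs {d2.dimension}"
        )
    p1, p2 = d1.pairs, d2.pairs
    if p1.size == 0 and p2.size == 0:
        return 0.0
    thetas = _slice_angles(n_slices)
    dirs = np.column_stack([np.cos(thetas), np.sin(thetas)])  # (S, 2)

    def diag_proj(p: np.ndarray) -> np.ndarray:
        mid = 0.5 * (p[:, 0] + p[:, 1])
        return np.column_stack([mid, mid])

    a = np.vstack([p1, diag_proj(p2)]) if p2.size else p1
    b = np.vstack([p2, diag_proj(p1)]) if p1.size else p2
    pa = np.sort(a @ dirs.T, axis=0)   # (m, S)
    pb = np.sort(b @ dirs.T, axis=0)
    return float(np.abs(pa - pb).sum(axis=0).mean())


def _padded_projections(diagrams: Sequence[PersistenceDiagram],
                        n_slices: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-diagram slice projections of points and of their diagonal images.

    Diagrams are padded with diagonal points (0, 0) to a common size; adding
    the same diagonal point to both sides of a comparison leaves the 1-D
    rank-matching cost unchanged, so padding is exact, and lets the pairwise
    matrix be computed with batched sorts.
    """
    thetas = _slice_angles(n_slices)
    dirs = np.column_stack([np.cos(thetas), np.sin(thetas)])
    m = max((d.n_pairs for d in diagrams), default=0)
    m = max(m, 1)
    n = len(diagrams)
    P = np.zeros((n, m, n_slices))
    Q = np.zeros((n, m, n_slices))
    for i, d in enumerate(diagrams):
        pts = d.pairs
        if pts.size:
            k = pts.shape[0]
            P[i, :k] = pts @ dirs.T
            mid = 0.5 * (pts[:, 0] + pts[:, 1])
            Q[i, :k] = np.column_stack([mid, mid]) @ dirs.T
    return P, Q


def _batched_sw(P: np.ndarray, Q: np.ndarray, idx_a: np.ndarray,
                idx_b: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Sliced-Wasserstein for index pairs, using precomputed projections."""
    out = np.empty(idx_a.size)
    for s in range(0, idx_a.size, chunk):
        ia = idx_a[s:s + chunk]
        ib = idx_b[s:s + chunk]
        side_a = np.concatenate([P[ia], Q[ib]], axis=1)  # (c, 2m, S)
        side_b = np.concatenate([P[ib], Q[ia]], axis=1)
        side_a.sort(axis=1)
        side_b.sort(axis=1)
        out[s:s + chunk] = np.abs(side_a - side_b).sum(axis=1).mean(axis=1)
    return out


def diagram_distance_matrix(diagrams: Sequence[PersistenceDiagram],
                            metric_name: str | None = None,
                            points: pd.DataFrame | None = None,
                            n_slices: int = defaults.N_SLICES) -> StateDistanceMatrix:
    """All-pairs sliced-Wasserstein matrix over same-dimension diagrams."""
    diagrams = list(diagrams)
    if not diagrams:
        raise ValueError("need at least one diagram")
    dims = {d.dimension for d in diagrams}
    if len(dims) > 1:
        raise ValueError(f"mixed diagram dimensions {sorted(dims)}")
    dim = dims.pop()
    name = metric_name or f"H{dim}"
    expected = f"H{dim}"
    if name != expected:
        raise ValueError(f"diagrams are dimension {dim}, not {name}")
    n = len(diagrams)
    P, Q = _padded_projections(diagrams, n_slices)
    iu, ju = np.triu_indices(n, k=1)
    vals = _batched_sw(P, Q, iu, ju)
    D = np.zeros((n, n))
    D[iu, ju] = vals
    D[ju, iu] = vals
    if points is None:
        points = pd.DataFrame(index=range(n))
    return StateDistanceMatrix(metric_name=name, D=D, points=points)


def diagram_cross_matrix(diagrams_a: Sequence[PersistenceDiagram],
                         diagrams_b: Sequence[PersistenceDiagram],
                         n_slices: int = defaults.N_SLICES) -> np.ndarray:
    """Rectangular sliced-Wasserstein block between two diagram lists."""
    dims = {d.dimension for d in diagrams_a} | {d.dimension for d in diagrams_b}
    if len(dims) > 1:
        raise ValueError(f"mixed diagram dimensions {sorted(dims)}")
    alld = list(diagrams_a) + list(diagrams_b)
    P, Q = _padded_projections(alld, n_slices)
    na, nb = len(diagrams_a), len(diagrams_b)
    ia, ib = np.meshgrid(np.arange(na), na + np.arange(nb), indexing="ij")
    vals = _batched_sw(P, Q, ia.ravel(), ib.ravel())
    return vals.reshape(na, nb)


def write_diagrams_csv(diagrams: Sequence[PersistenceDiagram], path) -> None:
    """Serialise diagrams as (dimension, birth, death) CSV; lossless round-trip."""
    rows = []
    for d in diagrams:
        for b, v in d.pairs:
            rows.append((d.dimension, repr(float(b)), repr(float(v))))
        rows.append((d.dimension, "essential", str(d.essential_count)))
    pd.DataFrame(rows, columns=["dimension", "birth", "death"]).to_csv(
        path, index=False)


def read_diagrams_csv(path) -> list[PersistenceDiagram]:
    df = pd.read_csv(path, dtype=str)
    out = []
    for dim, grp in df.groupby(df["dimension"].astype(int), sort=True):
        ess_rows = grp[grp["birth"] == "essential"]
        essential = int(ess_rows["death"].iloc[0]) if len(ess_rows) else 0
        fin = grp[grp["birth"] != "essential"]
        pairs = np.column_stack([
            fin["birth"].astype(float).to_numpy(),
            fin["death"].astype(float).to_numpy(),
        ]) if len(fin) else np.empty((0, 2))
        out.append(PersistenceDiagram(dimension=int(dim), pairs=pairs,
                                      essential_count=essential))
    return out
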
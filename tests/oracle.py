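"""Independent brute-force oracles used only by the test suite.

The persistence oracle reduces the *global* boundary matrix over GF(2) with
plain column sets (no clearing, no bitsets, no dimension splitting) so it
shares no code path with the production implementation. The
sliced-Wasserstein oracle is a literal per-slice loop.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_vr(D: np.ndarray, max_dim: int = 2):
    """Persistence of the Vietoris-Rips filtration by textbook reduction.

    Returns {dim: (list of (birth, death) pairs, essential count)}.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    simplices = []
    for d in range(0, max_dim + 2):
        for s in combinations(range(n), d + 1):
            if d == 0:
                val = 0.0
            else:
                val = max(D[a][b] for a, b in combinations(s, 2))
            simplices.append((val, d, s))
    simplices.sort(key=lambda t: (t[0], t[1], t[2]))
    index = {s: i for i, (_, _, s) in enumerate(simplices)}

    columns = []
    for val, d, s in simplices:
        if d == 0:
            columns.append(set())
        else:
            columns.append({index[f] for f in combinations(s, d)})

    low_of = {}
    pair_of = {}
    for j, col in enumerate(columns):
        col = set(col)
        while col:
            low = max(col)
            if low not in low_of:
                break
            col ^= columns[low_of[low]]
        columns[j] = col
        if col:
            low = max(col)
            low_of[low] = j
            pair_of[low] = j

    out = {}
    for dim in range(0, max_dim + 1):
        pairs = []
        essential = 0
        for j, (val, d, s) in enumerate(simplices):
            if d != dim:
                continue
            if columns[j]:
                continue  # negative simplex: kills a (d-1)-class
            if j in pair_of:
                death_val = simplices[pair_of[j]][0]
                if death_val > val:
                    pairs.append((val, death_val))
            else:
                essential += 1
        out[dim] = (sorted(pairs), essential)
    return out


def brute_force_sliced_wasserstein(p1: np.ndarray, p2: np.ndarray,
                                   n_slices: int = 20) -> float:
    """Literal per-slice loop: diagonal augmentation, projection, rank match."""
    p1 = np.asarray(p1, float).reshape(-1, 2)
    p2 = np.asarray(p2, float).reshape(-1, 2)
    if p1.size == 0 and p2.size == 0:
        return 0.0

    def diag(p):
        return [((b + d) / 2.0, (b + d) / 2.0) for b, d in p]

    a = [tuple(x) for x in p1] + diag(p2)
    b = [tuple(x) for x in p2] + diag(p1)
    total = 0.0
    for k in range(n_slices):
        theta = -np.pi / 2 + np.pi * k / n_slices
        vx, vy = np.cos(theta), np.sin(theta)
        pa = sorted(x * vx + y * vy for x, y in a)
        pb = sorted(x * vx + y * vy for x, y in b)
        total += sum(abs(u - v) for u, v in zip(pa, pb))
    return total / n_slices
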
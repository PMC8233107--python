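"""Subsampling/bootstrap schema and the permutation-test families.

Three disjoint volunteer groups per draw: one trains the 2-D embedding, one
segments it into watershed clusters, one supplies the tested points. Labels
(volunteer, condition, performance) are permuted to build empirical nulls,
summarised by their mean and standard deviation; Bonferroni correction uses
the stated comparison counts. All reported percentages come from the test
group only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import defaults, metrics as bm, topology, state_space
from .coherence import TVFCSeries

logger = logging.getLogger(__name__)


def retained_after_balancing(n_retained: int,
                             block_duration_s: float = defaults.BLOCK_DURATION,
                             tr: float = defaults.TR,
                             n_removed: int = defaults.N_REMOVED_PRESENTATIONS) -> int:
    """Per-volunteer point count after removing repeated task presentations.

    Removing one whole presentation each of the repeated tasks (each
    block_duration_s / tr samples long) from the retained time points.
    """
    per_block = round(block_duration_s / tr)
    out = n_retained - n_removed * per_block
    if out <= 0:
        raise ValueError("balancing removes every retained point")
    return out


# ---------------------------------------------------------------------------
# split plan


@dataclass
class SplitPlan:
    """One bootstrap draw's volunteer tripartition and temporal subsampling."""

    embed_group: list[str]
    cluster_group: list[str]
    test_group: list[str]
    retained_mask: dict[str, np.ndarray]      # per volunteer, over retained points
    train_subsample: dict[str, np.ndarray]    # per volunteer, indices into retained
    eval_subsample: dict[str, np.ndarray]     # per volunteer, indices into retained
    seed: int


def _condition_runs(conditions: np.ndarray, target: str) -> list[np.ndarray]:
    """Contiguous runs (presentations) of one condition, as index arrays."""
    idx = np.flatnonzero(conditions == target)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return np.split(idx, breaks + 1)


def _lattice(positions: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k indices from `positions` on an even lattice with random phase —
    a deterministic, seed-controlled reading of maximal temporal separation."""
    n = positions.size
    if n < k:
        raise ValueError(f"cannot draw {k} lattice points from {n} positions")
    step = n / k
    phase = rng.uniform(0.0, step)
    picks = np.minimum((phase + step * np.arange(k)).astype(int), n - 1)
    return positions[picks]


def make_split(tvfc_list: Sequence[TVFCSeries], seed: int,
               n_train: int = defaults.TRAIN_SUBSAMPLE,
               n_eval: int | None = None,
               balance_conditions: tuple[str, ...] = ("math", "memory")) -> SplitPlan:
    """Random equal tripartition of volunteers plus condition balancing.

    One randomly chosen presentation of each repeated task is removed from
    every volunteer; training points form an even temporal lattice with random
    phase. ``n_eval`` optionally subsamples the clustering/testing points the
    same way (desk-scale control; None keeps all retained points).
    """
    vols = [tv.point_meta["volunteer"].iloc[0] for tv in tvfc_list]
    if len(vols) < 3:
        raise ValueError("need at least 3 volunteers")
    if len(vols) % 3 != 0:
        raise ValueError(f"{len(vols)} volunteers cannot form three equal groups")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    order = rng.permutation(len(vols))
    g = len(vols) // 3
    groups = [sorted(vols[i] for i in order[j * g:(j + 1) * g]) for j in range(3)]

    retained_mask: dict[str, np.ndarray] = {}
    train_sub: dict[str, np.ndarray] = {}
    eval_sub: dict[str, np.ndarray] = {}
    for tv, vol in zip(tvfc_list, vols):
        conds = tv.point_meta["condition"].to_numpy()
        mask = np.ones(conds.size, dtype=bool)
        for target in balance_conditions:
            runs = _condition_runs(conds, target)
            if len(runs) < 2:
                raise ValueError(
                    f"volunteer {vol!r} lacks a repeated {target!r} presentation"
                )
            drop = runs[rng.integers(len(runs))]
            mask[drop] = False
        retained_mask[vol] = mask
        positions = np.flatnonzero(mask)
        train_sub[vol] = _lattice(positions, n_train, rng)
        if n_eval is None:
            eval_sub[vol] = positions
        else:
            eval_sub[vol] = _lattice(positions, min(n_eval, positions.size), rng)
    return SplitPlan(embed_group=groups[0], cluster_group=groups[1],
                     test_group=groups[2], retained_mask=retained_mask,
                     train_subsample=train_sub, eval_subsample=eval_sub,
                     seed=int(seed))


# ---------------------------------------------------------------------------
# permutation machinery


def _normal_p(obs: np.ndarray, mu: np.ndarray, sd: np.ndarray,
              tail: str) -> np.ndarray:
    """p-values from the (mean, sd) summary of a permutation null."""
    obs, mu, sd = np.broadcast_arrays(np.asarray(obs, float), mu, sd)
    p = np.ones_like(mu, dtype=float)
    nz = sd > 0
    z = np.zeros_like(mu)
    z[nz] = (obs[nz] - mu[nz]) / sd[nz]
    if tail == "right":
        p[nz] = norm.sf(z[nz])
        p[~nz] = np.where(obs[~nz] > mu[~nz], 0.0, 1.0)
    elif tail == "left":
        p[nz] = norm.cdf(z[nz])
        p[~nz] = np.where(obs[~nz] < mu[~nz], 0.0, 1.0)
    elif tail == "two":
        p[nz] = 2.0 * norm.sf(np.abs(z[nz]))
        p[~nz] = np.where(obs[~nz] != mu[~nz], 0.0, 1.0)
    else:
        raise ValueError("tail must be 'left', 'right' or 'two'")
    return p


def _empirical_p(obs: np.ndarray, null_counts: np.ndarray, tail: str) -> np.ndarray:
    """Rank-based p-values with the +1 correction; null_counts is (P, K, L)."""
    P = null_counts.shape[0]
    if tail == "right":
        ge = (null_counts >= obs[None]).sum(axis=0)
        return (ge + 1.0) / (P + 1.0)
    if tail == "left":
        le = (null_counts <= obs[None]).sum(axis=0)
        return (le + 1.0) / (P + 1.0)
    raise ValueError("empirical mode supports 'left' and 'right' tails")


def permutation_null(assignments: np.ndarray, labels: np.ndarray,
                     n_perm: int = defaults.N_PERMUTATIONS,
                     seed: int = 0,
                     keep_null_counts: bool = False) -> pd.DataFrame:
    """Permutation null of per-cluster label counts.

    Points with assignment 0 (outside every watershed cluster) are excluded.
    Returns one row per (cluster, label) with observed count, null mean and
    null sd over ``n_perm`` label permutations.
    """
    a = np.asarray(assignments)
    lab = np.asarray(labels)
    if a.shape != lab.shape:
        raise ValueError("assignments and labels must align")
    keep = a > 0
    a, lab = a[keep], lab[keep]
    clusters, ci = np.unique(a, return_inverse=True)
    labset, li = np.unique(lab, return_inverse=True)
    if clusters.size == 1 and labset.size == 1:
        warnings.warn("single cluster and single label: degenerate null")
    K, L = clusters.size, labset.size
    C = np.zeros((a.size, K))
    C[np.arange(a.size), ci] = 1.0
    onehot = np.zeros((a.size, L))
    onehot[np.arange(a.size), li] = 1.0
    observed = C.T @ onehot                      # (K, L)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    s = np.zeros((K, L))
    s2 = np.zeros((K, L))
    null_counts = np.empty((n_perm, K, L)) if keep_null_counts else None
    for p in range(n_perm):
        perm = rng.permutation(a.size)
        M = C.T @ onehot[perm]
        s += M
        s2 += M * M
        if keep_null_counts:
            null_counts[p] = M
    mu = s / n_perm
    var = np.maximum(s2 / n_perm - mu * mu, 0.0)
    sd = np.sqrt(var)
    rows = []
    for i, c in enumerate(clusters):
        for j, l in enumerate(labset):
            rows.append((c, l, observed[i, j], mu[i, j], sd[i, j]))
    df = pd.DataFrame(rows, columns=["cluster", "label", "observed",
                                     "null_mean", "null_sd"])
    if keep_null_counts:
        df.attrs["null_counts"] = null_counts
        df.attrs["clusters"] = clusters
        df.attrs["labels"] = labset
    return df


@dataclass
class ClusterTestResult:
    cluster_id: int
    label: object
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    significant: bool
    tail: str


# ---------------------------------------------------------------------------
# test families


@dataclass
class GeneralizabilityResult:
    """Per-cluster represented-volunteer counts and binned point percentages."""

    bins: dict[int, float]                 # bin b -> % of test points
    represented: dict[int, int]            # cluster -> number of represented vols
    table: pd.DataFrame
    n_volunteers: int


def volunteer_generalizability(assignments: np.ndarray, volunteers: np.ndarray,
                               alpha: float = defaults.ALPHA,
                               n_perm: int = defaults.N_PERMUTATIONS,
                               seed: int = 0,
                               p_mode: str = "normal") -> GeneralizabilityResult:
    """How many volunteers contribute a not-insignificant share to each cluster.

    A volunteer is *represented* in a cluster iff the left-tail
    underrepresentation test does NOT reject at the Bonferroni-corrected level
    alpha / (n_volunteers * n_clusters). Reports, for each bin b, the
    percentage of assigned test points lying in clusters with exactly b
    represented volunteers.
    """
    a = np.asarray(assignments)
    vols = np.asarray(volunteers)
    df = permutation_null(a, vols, n_perm=n_perm, seed=seed,
                          keep_null_counts=(p_mode == "empirical"))
    all_vols = np.unique(vols)
    V = all_vols.size
    clusters = np.unique(a[a > 0])
    K = clusters.size
    m = max(V * K, 1)
    if p_mode == "empirical":
        counts = df.attrs["null_counts"]
        pmat = _empirical_p(
            df.pivot(index="cluster", columns="label", values="observed").to_numpy(),
            counts, "left")
        pv = pd.DataFrame(pmat, index=df.attrs["clusters"],
                          columns=df.attrs["labels"]).stack()
        df["p_value"] = pv.loc[list(zip(df["cluster"], df["label"]))].to_numpy()
    else:
        df["p_value"] = _normal_p(df["observed"].to_numpy(),
                                  df["null_mean"].to_numpy(),
                                  df["null_sd"].to_numpy(), "left")
    df["significant"] = df["p_value"] < alpha / m
    df["tail"] = "left"

    # volunteers with no assigned test point at all cannot be represented
    missing = set(all_vols) - set(np.unique(vols[a > 0]))
    represented: dict[int, int] = {}
    for c in clusters:
        sub = df[df["cluster"] == c]
        under = set(sub.loc[sub["significant"], "label"])
        represented[int(c)] = int(V - len(under) - len(missing))

    assigned = a[a > 0]
    total = assigned.size
    bins = {b: 0.0 for b in range(0, V + 1)}
    for c in clusters:
        pct = 100.0 * (assigned == c).sum() / max(total, 1)
        bins[represented[int(c)]] += pct
    return GeneralizabilityResult(bins=bins, represented=represented,
                                  table=df, n_volunteers=V)


@dataclass
class EnrichmentResult:
    """Significant (cluster, condition) pairs and colocalization percentages."""

    significant: set[tuple[int, str]]
    colocalization: dict[str, float]       # condition -> % of its points
    table: pd.DataFrame
    n_clusters: int


def _colocalization(assignments: np.ndarray, conditions: np.ndarray,
                    significant: set[tuple[int, str]]) -> dict[str, float]:
    a = np.asarray(assignments)
    cond = np.asarray(conditions)
    out: dict[str, float] = {}
    for c in np.unique(cond):
        sel = cond == c
        n_c = sel.sum()
        if n_c == 0:
            out[str(c)] = 0.0
            continue
        sig_clusters = {cl for cl, cc in significant if cc == c}
        in_sig = np.isin(a[sel], list(sig_clusters)) if sig_clusters else \
            np.zeros(n_c, dtype=bool)
        out[str(c)] = 100.0 * in_sig.sum() / n_c
    return out


def stimulus_enrichment(assignments: np.ndarray, conditions: np.ndarray,
                        alpha: float = defaults.ALPHA,
                        n_perm: int = defaults.N_PERMUTATIONS,
                        seed: int = 0,
                        n_conditions: int | None = None,
                        p_mode: str = "normal") -> EnrichmentResult:
    """Right-tail enrichment of each condition in each watershed cluster.

    Bonferroni correction: number of stimulus conditions times number of
    clusters. Colocalization is the percentage of each condition's assigned
    points residing in clusters significantly enriched for it.
    """
    a = np.asarray(assignments)
    cond = np.asarray(conditions)
    present = np.unique(cond)
    n_cond = n_conditions if n_conditions is not None else present.size
    df = permutation_null(a, cond, n_perm=n_perm, seed=seed,
                          keep_null_counts=(p_mode == "empirical"))
    clusters = np.unique(a[a > 0])
    m = max(n_cond * clusters.size, 1)
    if p_mode == "empirical":
        counts = df.attrs["null_counts"]
        pmat = _empirical_p(
            df.pivot(index="cluster", columns="label", values="observed").to_numpy(),
            counts, "right")
        pv = pd.DataFrame(pmat, index=df.attrs["clusters"],
                          columns=df.attrs["labels"]).stack()
        df["p_value"] = pv.loc[list(zip(df["cluster"], df["label"]))].to_numpy()
    else:
        df["p_value"] = _normal_p(df["observed"].to_numpy(),
                                  df["null_mean"].to_numpy(),
                                  df["null_sd"].to_numpy(), "right")
    df["significant"] = df["p_value"] < alpha / m
    df["tail"] = "right"
    significant = {
        (int(r.cluster), str(r.label))
        for r in df.itertuples() if r.significant
    }
    coloc = _colocalization(a, cond, significant)
    for c in coloc:
        if (cond == c).sum() == 0:
            logger.warning("condition %r absent from the test set", c)
    return EnrichmentResult(significant=significant, colocalization=coloc,
                            table=df, n_clusters=int(clusters.size))


def permuted_colocalization(assignments: np.ndarray, conditions: np.ndarray,
                            significant: set[tuple[int, str]],
                            n_perm: int, seed: int) -> pd.DataFrame:
    """Yellow-box null: colocalization after permuting labels, keeping the
    pre-identified significant clusters fixed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    cond = np.asarray(conditions)
    rows = []
    for _ in range(n_perm):
        perm = rng.permutation(cond.size)
        rows.append(_colocalization(assignments, cond[perm], significant))
    return pd.DataFrame(rows)


def false_positive_colocalization(assignments: np.ndarray,
                                  conditions: np.ndarray,
                                  n_draws: int, seed: int,
                                  alpha: float = defaults.ALPHA,
                                  n_perm: int = defaults.N_PERMUTATIONS,
                                  n_conditions: int | None = None) -> pd.DataFrame:
    """Black-box null: permute labels, then rerun the whole enrichment test."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    cond = np.asarray(conditions)
    rows = []
    for d in range(n_draws):
        perm = rng.permutation(cond.size)
        res = stimulus_enrichment(assignments, cond[perm], alpha=alpha,
                                  n_perm=n_perm,
                                  seed=int(rng.integers(2 ** 31 - 1)),
                                  n_conditions=n_conditions)
        rows.append(res.colocalization)
    return pd.DataFrame(rows)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised mean difference with pooled SD; +/-inf on zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per distribution")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    diff = x.mean() - y.mean()
    if sp2 <= 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled variance; effect size reported as inf")
        return float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(sp2))


@dataclass
class EffectSizeResult:
    cohen_d: dict[str, float]
    real: pd.DataFrame
    permuted: pd.DataFrame
    false_positive: pd.DataFrame


def enrichment_effect_size(real_pcts: pd.DataFrame,
                           permuted_pcts: pd.DataFrame,
                           false_positive_pcts: pd.DataFrame) -> EffectSizeResult:
    """Cohen's d between the real and permuted colocalization distributions.

    ``real_pcts`` holds one row per bootstrap draw (columns = conditions);
    ``permuted_pcts`` the label-permuted null restricted to the significant
    clusters; ``false_positive_pcts`` the full-pipeline permuted null.
    """
    d = {}
    for c in real_pcts.columns:
        if c in permuted_pcts.columns:
            d[str(c)] = cohens_d(real_pcts[c].to_numpy(),
                                 permuted_pcts[c].to_numpy())
    return EffectSizeResult(cohen_d=d, real=real_pcts, permuted=permuted_pcts,
                            false_positive=false_positive_pcts)


@dataclass
class PerformanceResult:
    task: str
    table: pd.DataFrame                  # cluster, observed, null stats, p, valence
    high_clusters: list[int]
    low_clusters: list[int]


def performance_test(assignments: np.ndarray, conditions: np.ndarray,
                     performance: np.ndarray, task: str,
                     task_sig_clusters: Sequence[int],
                     alpha: float = defaults.ALPHA,
                     n_perm: int = defaults.N_PERMUTATIONS,
                     seed: int = 0,
                     bonferroni: bool = False) -> PerformanceResult:
    """Valence the task-significant clusters by block performance.

    Restricted to clusters already significantly enriched for ``task``; each
    is flagged high- or low-performance by a two-tailed test of the cluster's
    mean task performance against a permutation null (mean/sd of task
    performance). Mean-split valence: observed >= null mean counts as high.
    """
    a = np.asarray(assignments)
    cond = np.asarray(conditions)
    perf = np.asarray(performance, dtype=float)
    sel = (cond == task) & (a > 0) & np.isfinite(perf)
    if not task_sig_clusters:
        logger.info("no significant clusters for task %r", task)
        return PerformanceResult(task=task, table=pd.DataFrame(),
                                 high_clusters=[], low_clusters=[])
    av, pv_ = a[sel], perf[sel]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    m = len(task_sig_clusters) if bonferroni else 1
    rows = []
    high, low = [], []
    for c in task_sig_clusters:
        in_c = av == c
        if in_c.sum() == 0:
            continue
        obs = pv_[in_c].mean()
        null = np.empty(n_perm)
        for p in range(n_perm):
            null[p] = pv_[rng.permutation(pv_.size)[:in_c.sum()]].mean()
        mu, sd = null.mean(), null.std()
        pval = float(_normal_p(np.array([obs]), np.array([mu]),
                               np.array([sd]), "two")[0])
        sig = pval < alpha / m
        valence = "high" if obs >= mu else "low"
        if sig:
            (high if valence == "high" else low).append(int(c))
        rows.append((int(c), obs, mu, sd, pval, sig, valence))
    table = pd.DataFrame(rows, columns=["cluster", "observed", "null_mean",
                                        "null_sd", "p_value", "significant",
                                        "valence"])
    return PerformanceResult(task=task, table=table, high_clusters=high,
                             low_clusters=low)


# ---------------------------------------------------------------------------
# end-to-end bootstrap driver


@dataclass
class StudyFeatures:
    """Per-volunteer state features, computed once and reused across draws."""

    volunteers: list[str]
    meta: dict[str, pd.DataFrame]
    points: dict[str, list[bm.StatePoint]]
    diagrams: dict[tuple[str, int], list[topology.PersistenceDiagram]]
    graphs: dict[str, np.ndarray]
    region_labels: list[str]


def prepare_features(tvfc_list: Sequence[TVFCSeries],
                     metrics_used: Sequence[str],
                     weight_mode: str = "coherence",
                     force: bool = False) -> StudyFeatures:
    """Extract state points and persistence diagrams needed by the metrics."""
    need_pts = any(m in bm.SIMPLICIAL_METRICS for m in metrics_used)
    dims = sorted({int(m[1]) for m in metrics_used if m in bm.TOPOLOGICAL_METRICS})
    vols, meta, points, diagrams, graphs = [], {}, {}, {}, {}
    region_labels: list[str] = []
    for tv in tvfc_list:
        vol = tv.point_meta["volunteer"].iloc[0]
        vols.append(vol)
        meta[vol] = tv.point_meta.reset_index(drop=True)
        graphs[vol] = tv.graphs
        region_labels = tv.region_labels
        if need_pts:
            points[vol] = bm.extract_state_points(tv, weight_mode=weight_mode)
        if dims:
            max_dim = max(dims)
            dgms = topology.tvfc_diagrams(tv.graphs, max_dim=max_dim, force=force)
            for d in dims:
                diagrams[(vol, d)] = [per_t[d] for per_t in dgms]
    return StudyFeatures(volunteers=vols, meta=meta, points=points,
                         diagrams=diagrams, graphs=graphs,
                         region_labels=region_labels)


def _gather_meta(features: StudyFeatures, vols: Sequence[str],
                 sel: dict[str, np.ndarray]) -> pd.DataFrame:
    parts = [features.meta[v].iloc[sel[v]] for v in vols]
    return pd.concat(parts, ignore_index=True)


def _metric_blocks(features: StudyFeatures, metric: str,
                   train_vols: Sequence[str], train_sel: dict[str, np.ndarray],
                   other_vols: Sequence[str], other_sel: dict[str, np.ndarray],
                   n_slices: int = defaults.N_SLICES):
    """(square train matrix, rectangular other-to-train matrix) for a metric."""
    if metric in bm.SIMPLICIAL_METRICS:
        train_pts = [features.points[v][i] for v in train_vols
                     for i in train_sel[v]]
        other_pts = [features.points[v][i] for v in other_vols
                     for i in other_sel[v]]
        D = bm.simplicial_cross_distances(train_pts, train_pts, metric)
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        R = bm.simplicial_cross_distances(other_pts, train_pts, metric)
        return D, R
    dim = int(metric[1])
    train_d = [features.diagrams[(v, dim)][i] for v in train_vols
               for i in train_sel[v]]
    other_d = [features.diagrams[(v, dim)][i] for v in other_vols
               for i in other_sel[v]]
    D = topology.diagram_distance_matrix(train_d, metric_name=metric,
                                         n_slices=n_slices).D
    R = topology.diagram_cross_matrix(other_d, train_d, n_slices=n_slices)
    return D, R


@dataclass
class DrawResult:
    """Everything one bootstrap draw produces for one metric space."""

    metric: str
    seed: int
    n_clusters: int
    generalizability: GeneralizabilityResult
    enrichment: EnrichmentResult
    performance: dict[str, PerformanceResult]
    test_meta: pd.DataFrame
    test_assignments: np.ndarray
    plan: SplitPlan


def run_draw(features: StudyFeatures, metric: str, seed: int,
             n_train: int = defaults.TRAIN_SUBSAMPLE,
             n_eval: int | None = None,
             alpha: float = defaults.ALPHA,
             n_perm: int = defaults.N_PERMUTATIONS,
             n_neighbors: int = 15, min_dist: float = 0.1,
             grid_size: int = defaults.GRID_SIZE,
             bandwidth_factor: float = defaults.BANDWIDTH_FACTOR,
             n_conditions: int | None = None,
             plan: SplitPlan | None = None,
             run_performance: bool = True) -> DrawResult:
    """One reinitialisation: split, embed, segment, and test one metric space."""
    meta_list = [features.meta[v] for v in features.volunteers]
    if plan is None:
        # make_split consumes TVFC metadata only
        dummy = [
            TVFCSeries(graphs=np.zeros((len(m), 1, 1)),
                       retained_time_index=np.arange(len(m)),
                       retained_scales=np.empty(0), point_meta=m)
            for m in meta_list
        ]
        plan = make_split(dummy, seed, n_train=n_train, n_eval=n_eval)
    D_train, R_cluster = _metric_blocks(
        features, metric, plan.embed_group, plan.train_subsample,
        plan.cluster_group, plan.eval_subsample)
    _, R_test = _metric_blocks(
        features, metric, plan.embed_group, plan.train_subsample,
        plan.test_group, plan.eval_subsample)
    emb = state_space.fit_embedding(D_train, n_neighbors=n_neighbors,
                                    min_dist=min_dist, seed=seed)
    cluster_coords = state_space.project(emb, R_cluster)
    seg = state_space.density_and_watershed(cluster_coords, grid_size=grid_size,
                                            bandwidth_factor=bandwidth_factor)
    test_coords = state_space.project(emb, R_test)
    assignments = seg.assign(test_coords)
    test_meta = _gather_meta(features, plan.test_group, plan.eval_subsample)

    vols = test_meta["volunteer"].to_numpy()
    conds = test_meta["condition"].to_numpy()
    perf = test_meta["performance"].to_numpy(dtype=float)

    gen = volunteer_generalizability(assignments, vols, alpha=alpha,
                                     n_perm=n_perm, seed=seed + 1)
    enr = stimulus_enrichment(assignments, conds, alpha=alpha, n_perm=n_perm,
                              seed=seed + 2, n_conditions=n_conditions)
    perf_results: dict[str, PerformanceResult] = {}
    if run_performance:
        tasks = sorted({
            str(c) for c, p in zip(conds, perf) if np.isfinite(p)
        })
        for i, task in enumerate(tasks):
            sig = sorted({cl for cl, cc in enr.significant if cc == task})
            perf_results[task] = performance_test(
                assignments, conds, perf, task, sig, alpha=alpha,
                n_perm=n_perm, seed=seed + 3 + i)
    return DrawResult(metric=metric, seed=seed, n_clusters=seg.n_clusters,
                      generalizability=gen, enrichment=enr,
                      performance=perf_results, test_meta=test_meta,
                      test_assignments=assignments, plan=plan)


@dataclass
class BootstrapResult:
    """Aggregate over reinitialisations: means and 95% CIs per metric."""

    draws: dict[str, list[DrawResult]]
    colocalization: dict[str, pd.DataFrame]   # metric -> draws x conditions
    bins: dict[str, pd.DataFrame]             # metric -> draws x bins

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric, df in self.colocalization.items():
            for c in df.columns:
                x = df[c].to_numpy()
                half = 1.96 * x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0
                rows.append((metric, c, x.mean(), x.mean() - half, x.mean() + half))
        return pd.DataFrame(rows, columns=["metric", "condition",
                                           "mean_pct", "ci_lo", "ci_hi"])


def bootstrap_driver(features: StudyFeatures, metrics_used: Sequence[str],
                     n_boot: int = defaults.N_BOOTSTRAPS, seed: int = 0,
                     **draw_kwargs) -> BootstrapResult:
    """Repeat split -> embed -> segment -> tests with fresh seeds per draw."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 43]))
    draw_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n_boot)]
    draws: dict[str, list[DrawResult]] = {m: [] for m in metrics_used}
    for b, ds in enumerate(draw_seeds):
        plan = None
        for metric in metrics_used:
            try:
                res = run_draw(features, metric, ds, plan=plan, **draw_kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate with run index
                raise RuntimeError(f"bootstrap draw {b} ({metric}) failed") from exc
            plan = res.plan      # share the split across metrics within a draw
            draws[metric].append(res)
    coloc = {
        m: pd.DataFrame([d.enrichment.colocalization for d in draws[m]])
        for m in metrics_used
    }
    bins = {
        m: pd.DataFrame([d.generalizability.bins for d in draws[m]])
        for m in metrics_used
    }
    return BootstrapResult(draws=draws, colocalization=coloc, bins=bins)
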
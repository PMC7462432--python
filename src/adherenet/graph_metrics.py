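"""Nodal and global graph metrics on binarized connectomes.

Implements the unweighted metrics used throughout the analysis:

* clustering coefficient  C_i = 2 L_i / (K_i (K_i - 1)) with L_i the triangle
  count around node i and K_i its degree; C_i = 0 when K_i < 2,
* geodesic (hop-count) distances, infinity for disconnected pairs,
* global efficiency  E_glob = mean of 1/L_ij over ordered pairs (1/inf = 0),
* local efficiency   Eloc_i = E_glob of the subgraph induced by i's neighbours,
* degree centrality  D_i = row sum of the adjacency (the hubness measure),
* modularity Q of Louvain partitions, averaged over repeated seeded runs
  (partitions themselves are discarded),
* binarized system segregation over the five resting-state networks:
  S = (z_binw - z_binb) / z_binw, where z_binw is the realized within-network
  edge density averaged over networks and z_binb the realized between-network
  edge density (pooled over all between pairs by default; a per-pair average
  is available behind a flag).

Disconnected pairs contribute 0 to efficiency sums so that stringent
thresholds, which fragment the network, leave every metric defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import BinaryGraph, pearson_connectome, threshold_sweep
from .errors import SingletonSubnetworkError, UndefinedSegregationError
from .io_formats import AffiliationVector, RoiTimeSeriesSet, RunConfig

GLOBAL_SCOPE = "GLOBAL"

#: Global metric column names used in long-format tables.
GLOBAL_METRICS = (
    "mean_clustering",
    "global_efficiency",
    "mean_local_efficiency",
    "modularity_q",
    "system_segregation",
)
NODAL_METRICS = ("clustering", "local_efficiency", "degree")


@dataclass(frozen=True)
class ModularityResult:
    q_values: tuple[float, ...]

    @property
    def mean_q(self) -> float:
        return float(np.mean(self.q_values))


@dataclass(frozen=True)
class SegregationResult:
    z_binw: float
    z_binb: float

    @property
    def segregation(self) -> float:
        return (self.z_binw - self.z_binb) / self.z_binw


def degree_centrality(g: BinaryGraph) -> np.ndarray:
    """Integer degree per node (row sums of the adjacency)."""
    return g.adjacency.sum(axis=1).astype(int)


def clustering_coefficient(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i and the network mean C.

    C_i is the fraction of a node's neighbour pairs that are connected, i.e.
    the fraction of triangles around it; nodes of degree < 2 get C_i = 0.
    """
    a = g.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    # diag(A^3) counts each triangle through i twice (once per orientation)
    closed = ((a @ a) * a).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, closed / denom, 0.0)
    return c, float(c.mean())


def geodesic_distances(g: BinaryGraph) -> np.ndarray:
    """Hop-count shortest-path matrix; np.inf for disconnected pairs."""
    return _distances(g.adjacency)


def _distances(a: np.ndarray) -> np.ndarray:
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def _efficiency_from_adjacency(a: np.ndarray) -> float:
    """Sum of inverse hop distances over ordered pairs / n(n-1).

    Runs breadth-first search for all sources at once via boolean matrix
    products (reachability-by-level), which stays in BLAS and terminates after
    diameter-many products; unreached pairs contribute 0.
    """
    n = a.shape[0]
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    ab = a.astype(np.float32)
    reached = (ab > 0) | np.eye(n, dtype=bool)
    total = float(ab.sum())  # distance-1 pairs
    d = 1
    while True:
        nxt = (reached.astype(np.float32) @ ab) > 0
        nxt |= reached
        newly = nxt & ~reached
        cnt = int(newly.sum())
        if cnt == 0:
            break
        d += 1
        total += cnt / d
        reached = nxt
    return float(total / (n * (n - 1)))


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse geodesic distance over ordered node pairs (1/inf = 0)."""
    return _efficiency_from_adjacency(g.adjacency)


def local_efficiency(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node Eloc_i = efficiency of the neighbour-induced subgraph, and mean.

    Nodes with fewer than 2 neighbours get 0 (their neighbour subgraph has no
    pairs to connect).
    """
    a = g.adjacency
    n = a.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        eloc[i] = _efficiency_from_adjacency(sub)
    return eloc, float(eloc.mean())


def modularity_q(a: np.ndarray, membership: np.ndarray) -> float:
    """Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j) for one partition."""
    a = np.asarray(a, dtype=float)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    membership = np.asarray(membership)
    same = membership[:, None] == membership[None, :]
    expected = np.outer(k, k) / two_m
    return float(((a - expected) * same).sum() / two_m)


def modularity_louvain(g: BinaryGraph, reps: int = 150, seed: int = 0) -> ModularityResult:
    """Mean Q over ``reps`` independent seeded Louvain runs.

    Each repetition gets a seed derived deterministically from ``seed``. Q is
    recomputed from the returned partition with :func:`modularity_q`. An
    edgeless graph yields Q = 0 with a warning so sweeps at extreme thresholds
    never crash.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    a = g.adjacency
    if a.sum() == 0:
        warnings.warn("graph has no edges; modularity defined as 0", UserWarning,
                      stacklevel=2)
        return ModularityResult(tuple(0.0 for _ in range(reps)))
    graph = nx.from_numpy_array(a)
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps, dtype=np.uint32)
    qs = []
    for s in rep_seeds:
        communities = nx.community.louvain_communities(graph, seed=int(s))
        membership = np.empty(g.n, dtype=int)
        for label, members in enumerate(communities):
            membership[list(members)] = label
        qs.append(modularity_q(a, membership))
    return ModularityResult(tuple(qs))


def system_segregation(g: BinaryGraph, aff: AffiliationVector,
                       pairwise_between: bool = False) -> SegregationResult:
    """Binarized system segregation S = (z_binw - z_binb) / z_binw.

    z_binw: within-network edge count over possible within pairs, averaged
    across networks. z_binb: between-network edge count over possible between
    pairs, pooled across all network pairs (or averaged per pair with
    ``pairwise_between=True``). Raises when a network is a singleton or when
    no within-network edges exist (0 denominator).
    """
    idx = aff.indices(g.roi_labels)
    a = g.adjacency
    networks = np.unique(idx)
    sizes = np.array([(idx == s).sum() for s in networks])
    if (sizes < 2).any():
        bad = [aff.networks[s] for s, size in zip(networks, sizes) if size < 2]
        raise SingletonSubnetworkError(f"subnetworks with < 2 nodes: {bad}")

    within_densities = []
    for s in networks:
        members = np.flatnonzero(idx == s)
        possible = len(members) * (len(members) - 1) / 2
        realized = a[np.ix_(members, members)].sum() / 2
        within_densities.append(realized / possible)
    z_binw = float(np.mean(within_densities))

    if pairwise_between:
        densities = []
        for p, s in enumerate(networks):
            for t in networks[p + 1:]:
                mem_s = np.flatnonzero(idx == s)
                mem_t = np.flatnonzero(idx == t)
                densities.append(a[np.ix_(mem_s, mem_t)].sum() / (len(mem_s) * len(mem_t)))
        z_binb = float(np.mean(densities))
    else:
        between_realized = 0.0
        between_possible = 0.0
        for p, s in enumerate(networks):
            for t in networks[p + 1:]:
                mem_s = np.flatnonzero(idx == s)
                mem_t = np.flatnonzero(idx == t)
                between_realized += a[np.ix_(mem_s, mem_t)].sum()
                between_possible += len(mem_s) * len(mem_t)
        z_binb = float(between_realized / between_possible)

    if z_binw == 0.0:
        raise UndefinedSegregationError("no within-network edges: segregation undefined")
    return SegregationResult(z_binw, z_binb)


# ---------------------------------------------------------------------------
# Sweeps and cohort tables
# ---------------------------------------------------------------------------

def metrics_over_sweep(graphs: list[BinaryGraph], aff: AffiliationVector,
                       cfg: RunConfig, participant_id: str = "",
                       global_metrics: tuple[str, ...] = GLOBAL_METRICS,
                       nodal_metrics: tuple[str, ...] = NODAL_METRICS,
                       seed: int = 0) -> pd.DataFrame:
    """Long-format metric table for one participant's threshold sweep.

    Columns: participant_id, threshold, scope (node label or ``GLOBAL``),
    metric, value. Undefined system segregation (no within edges at a harsh
    threshold) is recorded as missing, not zero. ``global_metrics`` /
    ``nodal_metrics`` subset which metrics are computed, which keeps large
    simulation studies affordable when only a few metrics are scanned.
    """
    rows: list[tuple[str, float, str, str, float]] = []
    for g in graphs:
        t = g.threshold
        need_cluster = "clustering" in nodal_metrics or "mean_clustering" in global_metrics
        if need_cluster:
            c_i, c_mean = clustering_coefficient(g)
            if "clustering" in nodal_metrics:
                rows += [(participant_id, t, lab, "clustering", v)
                         for lab, v in zip(g.roi_labels, c_i)]
            if "mean_clustering" in global_metrics:
                rows.append((participant_id, t, GLOBAL_SCOPE, "mean_clustering", c_mean))
        if "degree" in nodal_metrics:
            d = degree_centrality(g)
            rows += [(participant_id, t, lab, "degree", float(v))
                     for lab, v in zip(g.roi_labels, d)]
        if "local_efficiency" in nodal_metrics or "mean_local_efficiency" in global_metrics:
            eloc_i, eloc_mean = local_efficiency(g)
            if "local_efficiency" in nodal_metrics:
                rows += [(participant_id, t, lab, "local_efficiency", v)
                         for lab, v in zip(g.roi_labels, eloc_i)]
            if "mean_local_efficiency" in global_metrics:
                rows.append((participant_id, t, GLOBAL_SCOPE, "mean_local_efficiency", eloc_mean))
        if "global_efficiency" in global_metrics:
            rows.append((participant_id, t, GLOBAL_SCOPE, "global_efficiency",
                         global_efficiency(g)))
        if "modularity_q" in global_metrics:
            q = modularity_louvain(g, reps=cfg.louvain_reps, seed=seed).mean_q
            rows.append((participant_id, t, GLOBAL_SCOPE, "modularity_q", q))
        if "system_segregation" in global_metrics:
            try:
                s = system_segregation(g, aff, pairwise_between=cfg.pairwise_between)
                value = s.segregation
            except UndefinedSegregationError:
                value = np.nan
            rows.append((participant_id, t, GLOBAL_SCOPE, "system_segregation", value))
    return pd.DataFrame(rows, columns=["participant_id", "threshold", "scope",
                                       "metric", "value"])


def cohort_metric_table(ts_sets: list[RoiTimeSeriesSet], aff: AffiliationVector,
                        cfg: RunConfig,
                        global_metrics: tuple[str, ...] = GLOBAL_METRICS,
                        nodal_metrics: tuple[str, ...] = NODAL_METRICS,
                        seed: int = 0) -> pd.DataFrame:
    """Connectome -> sweep -> metrics for every participant; one long table."""
    tables = []
    for p_idx, ts in enumerate(ts_sets):
        w = pearson_connectome(ts)
        graphs = threshold_sweep(w, cfg.threshold_grid, absolute=cfg.absolute_threshold)
        tables.append(
            metrics_over_sweep(graphs, aff, cfg, participant_id=ts.participant_id,
                               global_metrics=global_metrics,
                               nodal_metrics=nodal_metrics,
                               seed=seed + p_idx)
        )
    return pd.concat(tables, ignore_index=True)
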
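"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive -- O(n^3) loops, exhaustive enumeration
-- and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def triangles_around(a: np.ndarray, i: int) -> int:
    """Count triangles through node i by enumerating neighbour pairs."""
    nbrs = [j for j in range(a.shape[0]) if a[i, j]]
    return sum(1 for u, v in itertools.combinations(nbrs, 2) if a[u, v])


def clustering_oracle(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = int(a[i].sum())
        if k >= 2:
            out[i] = 2 * triangles_around(a, i) / (k * (k - 1))
    return out


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_oracle(a: np.ndarray) -> float:
    n = a.shape[0]
    d = floyd_warshall(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_oracle(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) >= 2:
            sub = a[np.ix_(nbrs, nbrs)]
            out[i] = global_efficiency_oracle(sub)
    return out


def degree_oracle(a: np.ndarray) -> np.ndarray:
    return np.array([sum(int(a[i, j]) for j in range(a.shape[0]))
                     for i in range(a.shape[0])])


def modularity_oracle(a: np.ndarray, membership) -> float:
    """Q from the definition, summed pair by pair."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    k = [a[i].sum() for i in range(n)]
    two_m = sum(k)
    if two_m == 0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def _set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1:]
        yield [[first]] + partition


def best_modularity_oracle(a: np.ndarray) -> float:
    """Optimal Q over every partition (feasible for n <= 8)."""
    n = a.shape[0]
    best = -np.inf
    for partition in _set_partitions(list(range(n))):
        membership = [0] * n
        for label, block in enumerate(partition):
            for node in block:
                membership[node] = label
        best = max(best, modularity_oracle(a, membership))
    return best


def segregation_oracle(a: np.ndarray, membership) -> tuple[float, float]:
    """(mean within density, pooled between density) by direct counting."""
    membership = list(membership)
    groups = sorted(set(membership))
    within = []
    for s in groups:
        members = [i for i, m in enumerate(membership) if m == s]
        possible = len(members) * (len(members) - 1) / 2
        realized = sum(a[u, v] for u, v in itertools.combinations(members, 2))
        within.append(realized / possible)
    between_realized = 0
    between_possible = 0
    for s, t in itertools.combinations(groups, 2):
        mem_s = [i for i, m in enumerate(membership) if m == s]
        mem_t = [i for i, m in enumerate(membership) if m == t]
        between_possible += len(mem_s) * len(mem_t)
        between_realized += sum(int(a[u, v]) for u in mem_s for v in mem_t)
    return float(np.mean(within)), between_realized / between_possible


def bh_stepup_oracle(p_values, q):
    """Benjamini-Hochberg rejections straight from the step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


def auc_concordance_oracle(scores, labels) -> float:
    """AUC as the normalized count of concordant pairs (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def pearson_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    upper = rng.random((n, n)) < p
    a = np.triu(upper, 1)
    return (a | a.T).astype(np.int8)
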
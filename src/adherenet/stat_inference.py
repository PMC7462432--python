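"""Permutation correlation scans against adherence, with BH-FDR correction.

Association between a network metric and an adherence score is measured by
Pearson r, with significance from a two-sided permutation test: y is permuted
n_perm times and p is the add-one estimator

    p = (1 + #{ permutations with |r_perm| >= |r_obs| }) / (n_perm + 1),

so the smallest attainable p is exactly 1/(n_perm + 1) -- with the standard
1,000 permutations that floor is 9.99e-4 -- and p = 0 is never reported. The
test is two-sided because both positive (clustering, segregation) and negative
(global efficiency, some hubs) associations are scientifically expected.

Multiple testing is corrected with Benjamini-Hochberg FDR. The correction
family is: all nodes within one threshold for nodal scans, and all global
metrics x thresholds within one (group, outcome) for global scans; the family
used is recorded in every result. Nodes significant at >= min_sig_thresholds
thresholds form the robust set (default 3; set to the full grid length for the
strict whole-range rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConstantVectorError
from .graph_metrics import GLOBAL_SCOPE
from .io_formats import AdherenceRecord, AffiliationVector, RunConfig

#: Global metrics scanned against adherence, with the direction the modular
#: generative model implies (segregation-type metrics rise with coupling,
#: integration falls).
DEFAULT_GLOBAL_SCAN_METRICS = (
    "mean_clustering",
    "global_efficiency",
    "mean_local_efficiency",
    "system_segregation",
)

RESULT_COLUMNS = ["scope", "metric", "threshold", "group", "outcome",
                  "r", "p", "q", "significant"]


@dataclass(frozen=True)
class RobustNodeSet:
    """Nodes significant after FDR at >= min_sig_thresholds thresholds."""

    metric: str
    group: str
    outcome: str
    min_sig_thresholds: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(n for n, c in self.counts.items()
                            if c >= self.min_sig_thresholds))


def _pearson(xz: np.ndarray, yz: np.ndarray) -> float:
    return float(xz @ yz / len(xz))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ConstantVectorError("constant vector: correlation undefined")
    return (v - v.mean()) / sd


def permutation_correlation(x: Sequence[float], y: Sequence[float],
                            n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Pearson r and its two-sided permutation p-value (add-one estimator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xz, yz = _zscore(x), _zscore(y)
    r = _pearson(xz, yz)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yz, (n_perm, 1)), axis=1)
    r_perm = perms @ xz / len(x)
    # >= with a float-noise guard so genuinely tied statistics count as extreme
    exceed = int(np.sum(np.abs(r_perm) >= np.abs(r) - 1e-12))
    p = (1 + exceed) / (n_perm + 1)
    return r, p


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (monotone q-values, significance mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def _derived_seed(base_seed: int, *parts: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed), *[int(p) for p in parts]])


def _perm_pvalues_matrix(X: np.ndarray, y: np.ndarray, n_perm: int,
                         base_seed: int, tag: int) -> tuple[np.ndarray, np.ndarray]:
    """Permutation test of each column of X against y; per-test derived seeds."""
    n, m = X.shape
    yz = _zscore(y)
    r_obs = np.empty(m)
    p_obs = np.empty(m)
    for j in range(m):
        xz = _zscore(X[:, j])
        r = _pearson(xz, yz)
        rng = np.random.default_rng(_derived_seed(base_seed, tag, j))
        perms = rng.permuted(np.tile(yz, (n_perm, 1)), axis=1)
        r_perm = perms @ xz / n
        exceed = int(np.sum(np.abs(r_perm) >= np.abs(r) - 1e-12))
        r_obs[j] = r
        p_obs[j] = (1 + exceed) / (n_perm + 1)
    return r_obs, p_obs


def _select_participants(records: Sequence[AdherenceRecord], group: str) -> list[AdherenceRecord]:
    if group == "all":
        chosen = list(records)
    else:
        chosen = [r for r in records if r.group == group]
    if len(chosen) < 3:
        raise ValueError(f"group {group!r} has < 3 participants")
    return chosen


def _outcome_vector(records: Sequence[AdherenceRecord], outcome: str) -> np.ndarray:
    return np.array([getattr(r, outcome) for r in records], dtype=float)


def _metric_matrix(metric_table: pd.DataFrame, participant_ids: Sequence[str],
                   metric: str, threshold: float,
                   scopes: Sequence[str]) -> np.ndarray:
    sub = metric_table[
        (metric_table["metric"] == metric)
        & (np.isclose(metric_table["threshold"], threshold))
    ]
    pivot = sub.pivot(index="participant_id", columns="scope", values="value")
    return pivot.loc[list(participant_ids), list(scopes)].to_numpy()


def nodal_scan(metric_table: pd.DataFrame, adherence: Sequence[AdherenceRecord],
               cfg: RunConfig, group: str = "all", outcome: str = "homework",
               metric: str = "clustering", seed: int = 0
               ) -> tuple[pd.DataFrame, RobustNodeSet]:
    """Node-by-node permutation scan of one nodal metric against adherence.

    Within each threshold, all nodes are tested and BH-FDR is applied across
    the nodes of that threshold. Returns the full association table and the
    robust-node set (significant at >= cfg.min_sig_thresholds thresholds).
    """
    records = _select_participants(adherence, group)
    ids = [r.participant_id for r in records]
    y = _outcome_vector(records, outcome)
    nodes = sorted(set(metric_table.loc[metric_table["scope"] != GLOBAL_SCOPE, "scope"]))

    if cfg.min_sig_thresholds > len(cfg.threshold_grid):
        warnings.warn(
            f"min_sig_thresholds={cfg.min_sig_thresholds} exceeds the "
            f"{len(cfg.threshold_grid)}-threshold grid: robust set is provably empty",
            UserWarning,
            stacklevel=2,
        )

    frames = []
    counts: dict[str, int] = {n: 0 for n in nodes}
    for t_idx, t in enumerate(cfg.threshold_grid):
        X = _metric_matrix(metric_table, ids, metric, t, nodes)
        valid = np.flatnonzero(np.nanstd(X, axis=0) > 0)
        r = np.full(len(nodes), np.nan)
        p = np.full(len(nodes), np.nan)
        if valid.size:
            r_v, p_v = _perm_pvalues_matrix(X[:, valid], y, cfg.n_perm, seed, t_idx)
            r[valid], p[valid] = r_v, p_v
        q = np.full(len(nodes), np.nan)
        sig = np.zeros(len(nodes), dtype=bool)
        if valid.size:
            q_v, sig_v = fdr_bh(p[valid], cfg.fdr_q)
            q[valid], sig[valid] = q_v, sig_v
        for node in np.array(nodes)[sig]:
            counts[node] += 1
        frames.append(pd.DataFrame({
            "scope": nodes, "metric": metric, "threshold": t, "group": group,
            "outcome": outcome, "r": r, "p": p, "q": q, "significant": sig,
        }))
    results = pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]
    robust = RobustNodeSet(metric, group, outcome, cfg.min_sig_thresholds,
                           {n: c for n, c in counts.items() if c > 0})
    return results, robust


def global_scan(metric_table: pd.DataFrame, adherence: Sequence[AdherenceRecord],
                cfg: RunConfig, group: str = "all", outcome: str = "homework",
                metrics: Sequence[str] = DEFAULT_GLOBAL_SCAN_METRICS,
                seed: int = 0) -> pd.DataFrame:
    """Permutation scan of global metrics across the threshold grid.

    BH-FDR is applied across the whole family of (metric, threshold) cells for
    this group/outcome. Cells whose metric is undefined (e.g. segregation at a
    threshold with no within edges for some participant) are dropped from the
    family and reported with missing p/q.
    """
    records = _select_participants(adherence, group)
    ids = [r.participant_id for r in records]
    y = _outcome_vector(records, outcome)

    rows = []
    for t_idx, t in enumerate(cfg.threshold_grid):
        for m_idx, metric in enumerate(metrics):
            X = _metric_matrix(metric_table, ids, metric, t, [GLOBAL_SCOPE])
            x = X[:, 0]
            if np.isnan(x).any() or np.std(x) == 0:
                rows.append((GLOBAL_SCOPE, metric, t, group, outcome,
                             np.nan, np.nan))
                continue
            tag = 10_000 + t_idx * 1000 + m_idx
            r_v, p_v = _perm_pvalues_matrix(x[:, None], y, cfg.n_perm, seed, tag)
            rows.append((GLOBAL_SCOPE, metric, t, group, outcome,
                         float(r_v[0]), float(p_v[0])))
    results = pd.DataFrame(rows, columns=["scope", "metric", "threshold",
                                          "group", "outcome", "r", "p"])
    results["q"] = np.nan
    results["significant"] = False
    defined = results["p"].notna()
    if defined.any():
        q_v, sig_v = fdr_bh(results.loc[defined, "p"].to_numpy(), cfg.fdr_q)
        results.loc[defined, "q"] = q_v
        results.loc[defined, "significant"] = sig_v
    return results[RESULT_COLUMNS]


def network_summary(robust: RobustNodeSet, aff: AffiliationVector) -> dict[str, int]:
    """Count robust nodes per resting-state network (bar-graph data)."""
    counts = {network: 0 for network in aff.networks}
    for node in robust.nodes:
        counts[aff.network_of(node)] += 1
    return counts
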
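"""Permutation-based group comparison of network metrics, with FDR.

Group-level covariance networks have no subject-level metric variance, so
group differences are tested by permuting diagnosis labels and re-running
the entire construction chain — residualization (refit inside each
shuffle when the scope is per-group, so label-dependent fits cannot
leak), association matrix, density thresholding, metric — for every
permutation. The two-tailed p-value uses the add-one convention
p = (1 + #{|null| >= |obs|}) / (n_perm + 1), so p is never exactly zero.

Nodal metrics are tested per node and corrected with Benjamini-Hochberg
FDR across the 68 nodes, separately for each metric and density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import CohortTable
from .residualize import DEFAULT_COVARIATES, residualize_matrix
from .network import edge_count_at_density
from . import metrics as _metrics

GLOBAL_METRICS = ("global_efficiency", "local_efficiency",
                  "clustering", "modularity", "small_world")
NODAL_METRICS = ("nodal_efficiency", "nodal_clustering", "closeness")


@dataclass(frozen=True)
class PermutationResult:
    """Observed difference (patient - control) against a permutation null."""

    metric: str
    density: float
    scope: str              # "global" or a region id
    observed: float
    p_value: float
    n_perm: int
    null_mean: float
    null_lo: float          # 2.5 percentile
    null_hi: float          # 97.5 percentile
    seed: int | None = None


@dataclass(frozen=True)
class FdrResult:
    """Benjamini-Hochberg adjusted q-values and significance flags."""

    p_values: np.ndarray = field(repr=False)
    q_values: np.ndarray = field(repr=False)
    flags: np.ndarray = field(repr=False)
    q_threshold: float = 0.05


def fdr_bh(p_values, q_threshold: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up adjustment of a p-value family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return FdrResult(p_values=p, q_values=q, flags=q < q_threshold,
                     q_threshold=q_threshold)


# ---------------------------------------------------------------------------
# fast label-permutation chain: residualize -> correlate -> threshold -> metric

class _PermutationEngine:
    """Precomputed arrays for repeated chain evaluation under shuffles."""

    def __init__(self, cohort: CohortTable, covariates=DEFAULT_COVARIATES,
                 scope: str = "per_group"):
        self.thickness = cohort.thickness()
        self.scope = scope
        self.n = self.thickness.shape[0]
        self.n_regions = self.thickness.shape[1]
        self.is_patient = (cohort.data["group"] == "patient").to_numpy()
        if self.is_patient.sum() < 3 or (~self.is_patient).sum() < 3:
            raise ValueError("need at least 3 subjects per group")
        cols = [np.ones(self.n)]
        for cov in covariates:
            if cov == "mean_thickness":
                cols.append(self.thickness.mean(axis=1))
            else:
                cols.append(cohort.data[cov].to_numpy(dtype=float))
        self.design = np.column_stack(cols)
        if self.scope == "pooled":
            self._pooled_residuals = residualize_matrix(self.thickness,
                                                        self.design)

    def _adjacency(self, rows: np.ndarray, density: float) -> np.ndarray:
        if self.scope == "pooled":
            resid = self._pooled_residuals[rows]
        else:
            resid = residualize_matrix(self.thickness[rows],
                                       self.design[rows])
        r = np.corrcoef(resid, rowvar=False)
        np.fill_diagonal(r, 0.0)
        iu, ju = np.triu_indices(self.n_regions, k=1)
        order = np.argsort(-r[iu, ju], kind="stable")
        n_edges = edge_count_at_density(density, self.n_regions)
        adj = np.zeros((self.n_regions, self.n_regions), dtype=bool)
        adj[iu[order[:n_edges]], ju[order[:n_edges]]] = True
        return adj | adj.T

    def difference(self, labels_patient: np.ndarray, density: float,
                   metric_fn) -> np.ndarray:
        """metric(patient graph) - metric(control graph) under the labels."""
        adj_c = self._adjacency(~labels_patient, density)
        adj_p = self._adjacency(labels_patient, density)
        return np.asarray(metric_fn(adj_p)) - np.asarray(metric_fn(adj_c))


def _metric_function(metric: str, seed: int | None, n_random: int,
                     louvain_restarts: int):
    if metric == "global_efficiency":
        return _metrics.global_efficiency, True
    if metric == "local_efficiency":
        return (lambda a: _metrics.local_efficiency(a)[0]), True
    if metric == "clustering":
        return (lambda a: _metrics.clustering_coefficient(a)[0]), True
    if metric == "modularity":
        from .community import louvain_partition

        def _q(a):
            p = louvain_partition(a, seed=0 if seed is None else seed,
                                  n_restarts=louvain_restarts)
            return p.modularity
        return _q, True
    if metric == "small_world":
        return (lambda a: _metrics.small_world_index(
            a, n_random=n_random, seed=seed).sigma), True
    if metric == "nodal_efficiency":
        return _metrics.nodal_efficiency, False
    if metric == "nodal_clustering":
        return (lambda a: _metrics.clustering_coefficient(a)[1]), False
    if metric == "closeness":
        return _metrics.closeness_centrality, False
    raise ValueError(f"unknown metric: {metric!r}")


def permutation_test(cohort: CohortTable, metric: str, density: float,
                     n_perm: int = 5000, seed: int | None = 0,
                     covariates=DEFAULT_COVARIATES,
                     scope: str = "per_group",
                     n_random: int = 20,
                     louvain_restarts: int = 4,
                     q_threshold: float = 0.05):
    """Permutation test of a patient-vs-control metric difference.

    Global metrics return a single :class:`PermutationResult`; nodal
    metrics return ``(list of per-node PermutationResult, FdrResult)``
    with BH correction across nodes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    engine = _PermutationEngine(cohort, covariates=covariates, scope=scope)
    fn, is_global = _metric_function(metric, seed, n_random,
                                     louvain_restarts)
    observed = engine.difference(engine.is_patient, density, fn)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm,) + np.shape(observed))
    labels = engine.is_patient.copy()
    for b in range(n_perm):
        null[b] = engine.difference(rng.permutation(labels), density, fn)
    exceed = (np.abs(null) >= np.abs(observed)).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)

    lo, hi = np.percentile(null, [2.5, 97.5], axis=0)
    mean = null.mean(axis=0)
    if is_global:
        return PermutationResult(
            metric=metric, density=float(density), scope="global",
            observed=float(observed), p_value=float(p), n_perm=n_perm,
            null_mean=float(mean), null_lo=float(lo), null_hi=float(hi),
            seed=seed)
    regions = cohort.atlas.regions
    results = [
        PermutationResult(metric=metric, density=float(density),
                          scope=regions[j], observed=float(observed[j]),
                          p_value=float(p[j]), n_perm=n_perm,
                          null_mean=float(mean[j]), null_lo=float(lo[j]),
                          null_hi=float(hi[j]), seed=seed)
        for j in range(len(regions))
    ]
    return results, fdr_bh(p, q_threshold=q_threshold)


def random_graph_comparison(graphs, n_random: int = 200,
                            seed: int | None = 0) -> pd.DataFrame:
    """Z-scores of observed metrics against two random-graph ensembles.

    Each graph in the density sweep is compared with (a) Erdos-Renyi
    G(n, m) graphs with the same node and edge counts and (b)
    degree-preserving rewirings; a finding that survives against Controls
    but sits inside these nulls would be suspect.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    rows = []
    for g in graphs:
        a = _metrics._as_adjacency(g)
        n, m = a.shape[0], int(a.sum()) // 2
        observed = {
            "clustering": _metrics.clustering_coefficient(a)[0],
            "global_efficiency": _metrics.global_efficiency(a),
        }
        ensembles = {}
        er_seeds = rng.integers(0, 2**31 - 1, size=n_random)
        ensembles["erdos_renyi"] = [
            nx.to_numpy_array(nx.gnm_random_graph(n, m, seed=int(s)))
            .astype(bool)
            for s in er_seeds]
        ensembles["degree_preserving"] = [
            _metrics.degree_preserving_rewire(a, rng)
            for _ in range(n_random)]
        for name, ensemble in ensembles.items():
            for metric, fn in (
                    ("clustering",
                     lambda x: _metrics.clustering_coefficient(x)[0]),
                    ("global_efficiency", _metrics.global_efficiency)):
                vals = np.array([fn(e) for e in ensemble])
                sd = vals.std(ddof=1)
                z = (observed[metric] - vals.mean()) / sd if sd > 0 \
                    else float("inf")
                rows.append({
                    "density": getattr(g, "density", float("nan")),
                    "group": getattr(g, "group", ""),
                    "ensemble": name,
                    "metric": metric,
                    "observed": observed[metric],
                    "null_mean": vals.mean(),
                    "null_sd": sd,
                    "z": z,
                })
    return pd.DataFrame.from_records(rows)
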
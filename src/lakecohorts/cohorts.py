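"""Cohorts: modularity clustering of the co-occurrence graph, rewiring
nulls, connectedness and environmental preference.

Communities are found by Clauset–Newman–Moore greedy modularity
agglomeration on the unweighted co-occurrence graph. Modularity
``Q = sum_c [e_c/m - (d_c/2m)^2]`` is tested against a null ensemble of
degree-preserving randomly rewired graphs (attempted double-edge swaps,
rejecting swaps that would create loops or parallel edges), each rewired
graph being re-clustered from scratch — the stricter null. Communities of
at least six members are kept as "cohorts": groups of species that
co-occur and co-vary across samples. A cohort's environmental preference
for a covariate is the abundance-weighted average of the covariate's
z-score across samples, so positive values mean the cohort concentrates
its abundance in above-baseline samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .errors import DomainError

__all__ = [
    "CohortAssignment",
    "graph_from_edges",
    "cluster_greedy_modularity",
    "modularity_significance",
    "extract_cohorts",
    "degree_within_cohort",
    "environmental_preference",
]


@dataclass
class CohortAssignment:
    """Node-to-community map with modularity and its permutation p-value."""

    communities: list[set]
    modularity_q: float
    cohort_of: dict  # node -> "cohort_<i>" or "background"
    q_pvalue: float | None = None
    n_perm: int | None = None
    rewiring_iters: int | None = None
    min_size: int = 6

    @property
    def cohorts(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for node, label in self.cohort_of.items():
            if label != "background":
                out.setdefault(label, set()).add(node)
        return out


def graph_from_edges(edges: pd.DataFrame, nodes=None) -> nx.Graph:
    """Build the simple co-occurrence graph from an edge list
    (``source, target`` columns); optionally add isolated ``nodes``."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(zip(edges["source"], edges["target"]))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def cluster_greedy_modularity(graph: nx.Graph) -> tuple[list[set], float]:
    """CNM greedy agglomeration; returns the max-Q partition and Q.

    Starts from singletons and repeatedly merges the community pair with
    the largest modularity gain, keeping the partition at maximum Q. A
    graph with no edges yields singletons and Q = 0.
    """
    if graph.number_of_nodes() == 0:
        raise DomainError("empty graph")
    if graph.number_of_edges() == 0:
        return [{n} for n in graph.nodes], 0.0
    communities = [set(c) for c in nx.community.greedy_modularity_communities(graph)]
    q = nx.community.modularity(graph, communities)
    return communities, q


def _rewire(graph: nx.Graph, n_attempts: int, rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving rewiring by attempted double-edge swaps.

    Each attempt picks two distinct edges (a, b) and (c, d) and proposes
    (a, d), (c, b); the swap is rejected if it would create a self-loop or
    a parallel edge. Every node's degree is preserved exactly.
    """
    h = graph.copy()
    edges = list(h.edges())
    n_edges = len(edges)
    if n_edges < 2:
        return h
    for _ in range(n_attempts):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if h.has_edge(a, d) or h.has_edge(c, b):
            continue
        h.remove_edge(a, b)
        h.remove_edge(c, d)
        h.add_edge(a, d)
        h.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return h


def modularity_significance(
    graph: nx.Graph,
    n_perm: int = 500,
    rewiring_iters: int = 1000,
    seed: int | None = None,
    return_null: bool = False,
):
    """Permutation p-value of the observed modularity.

    Each permutation rewires the graph (``rewiring_iters`` attempted
    degree-preserving double-edge swaps), re-clusters it with the same
    greedy agglomeration, and records the null Q. The p-value is the raw
    proportion of null Q at least as large as the observed Q (so a graph
    more modular than every rewired null gets p = 0).
    """
    if graph.number_of_edges() < 2:
        warnings.warn("graph has < 2 edges; no rewiring is possible, p = 1")
        return (1.0, []) if return_null else 1.0
    _, q_obs = cluster_greedy_modularity(graph)
    degrees = dict(graph.degree())
    null_q = []
    for b in range(n_perm):
        rng = np.random.default_rng([0 if seed is None else seed, b])
        h = _rewire(graph, rewiring_iters, rng)
        assert dict(h.degree()) == degrees, "rewiring changed a node degree"
        _, q = cluster_greedy_modularity(h)
        null_q.append(q)
    p = float(np.mean(np.asarray(null_q) >= q_obs))
    return (p, null_q) if return_null else p


def extract_cohorts(communities: list[set], min_size: int = 6) -> dict:
    """Label communities of >= ``min_size`` members cohort_1..k by
    descending size (ties broken by smallest member id); everything else
    is background. Returns node -> label."""
    big = [c for c in communities if len(c) >= min_size]
    big.sort(key=lambda c: (-len(c), min(map(str, c))))
    cohort_of = {}
    for k, comm in enumerate(big, start=1):
        for node in comm:
            cohort_of[node] = f"cohort_{k}"
    for comm in communities:
        for node in comm:
            cohort_of.setdefault(node, "background")
    return cohort_of


def degree_within_cohort(graph: nx.Graph, cohort_of: dict) -> pd.Series:
    """Degree of each cohort member in its cohort's induced subgraph.

    Cross-cohort and cohort-to-background edges do not count. Background
    nodes are not reported.
    """
    rows = {}
    cohorts: dict[str, set] = {}
    for node, label in cohort_of.items():
        if label != "background":
            cohorts.setdefault(label, set()).add(node)
    for label, members in cohorts.items():
        sub = graph.subgraph(members)
        for node in members:
            rows[node] = sub.degree(node) if node in sub else 0
    return pd.Series(rows, name="degree_within_cohort", dtype=int).sort_index()


def export_graphml(graph: nx.Graph, cohort_of: dict, path) -> None:
    """Write the co-occurrence graph as GraphML with a ``cohort`` node
    attribute for downstream visualisation."""
    h = graph.copy()
    nx.set_node_attributes(
        h, {n: cohort_of.get(n, "background") for n in h.nodes}, name="cohort"
    )
    nx.write_graphml(h, path)


def environmental_preference(
    matrix: AbundanceMatrix,
    cohort_of: dict,
    params: pd.DataFrame,
    zscore_first: bool = True,
) -> pd.DataFrame:
    """Cohort x parameter matrix of abundance-weighted z-score averages.

    Each parameter is z-scored across samples (sample sd); the preference
    of cohort c for a parameter is ``sum_s w_cs z_s / sum_s w_cs`` with
    ``w_cs`` the summed relative abundance of the cohort's members in
    sample s. Samples with a missing parameter value are dropped for that
    parameter. A parameter with zero variance is reported as NaN.
    ``zscore_first=False`` instead computes the weighted average of the
    raw parameter and z-scores the resulting cohort values against the
    per-sample parameter distribution.
    """
    ab = matrix.abundance
    samples = ab.columns.intersection(params.index)
    if len(samples) == 0:
        raise DomainError("no overlap between abundance samples and parameter table")
    cohorts = sorted({v for v in cohort_of.values() if v != "background"})
    weights = pd.DataFrame(
        {
            c: ab.loc[[g for g, lab in cohort_of.items() if lab == c and g in ab.index]].sum(axis=0)
            for c in cohorts
        }
    ).T  # cohorts x samples
    out = pd.DataFrame(index=cohorts, columns=params.columns, dtype=float)
    for param in params.columns:
        x = params.loc[samples, param].astype(float)
        ok = x.notna()
        if ok.sum() < 2 or x[ok].std(ddof=1) == 0:
            warnings.warn(f"parameter {param!r} has no variance; preference undefined")
            out[param] = np.nan
            continue
        if zscore_first:
            z = (x[ok] - x[ok].mean()) / x[ok].std(ddof=1)
            w = weights.loc[:, ok.index[ok]]
            out[param] = (w * z).sum(axis=1) / w.sum(axis=1)
        else:
            w = weights.loc[:, ok.index[ok]]
            raw = (w * x[ok]).sum(axis=1) / w.sum(axis=1)
            out[param] = (raw - x[ok].mean()) / x[ok].std(ddof=1)
    return out
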
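"""Signed co-abundance network and hierarchical module assignment.

Nodes are the union of proteins called significant in any mutant-vs-WT or
mutant-vs-mutant contrast; edges connect pairs whose abundance profiles
across all samples correlate at |r| >= 0.95 (Pearson), keeping the sign.
Modules come from average-linkage agglomerative clustering of z-scored
profiles under the correlation distance 1 - r, cut to a fixed number of
clusters (default 12), with module ids ordered by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_core import AbundanceMatrix, Config, logger
from .differential import DifferentialResult


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    r: float
    sign: str  # "+" or "-"


@dataclass
class CoabundanceNetwork:
    nodes: list[str]
    edges: list[Edge]
    modules: dict[str, int] = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target, {"r": e.r, "sign": e.sign}) for e in self.edges)
        return g


def select_network_input(
    contrast_results: list[list[DifferentialResult]],
    use_q: bool = False,
    config: Config | None = None,
) -> set[str]:
    """Union of proteins with status up/down in at least one contrast."""
    config = config or Config()
    selected: set[str] = set()
    for results in contrast_results:
        for r in results:
            if r.status in ("up", "down"):
                if use_q and r.q_value > config.q_threshold:
                    continue
                selected.add(r.protein_id)
    if not selected:
        logger.warning("no protein significant in any contrast; network will be empty")
    return selected


def _transform(values: np.ndarray, mode: str) -> np.ndarray:
    if mode == "log10":
        return np.log10(np.maximum(values, 1e-12))
    if mode == "zscore":
        v = np.log10(np.maximum(values, 1e-12))
        sd = v.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (v - v.mean(axis=1, keepdims=True)) / sd
    return values


def correlation_edges(
    matrix: AbundanceMatrix,
    cutoff: float = 0.95,
    transform: str = "log10",
) -> list[Edge]:
    """Pearson correlation per unordered pair of protein profiles; keep
    r >= cutoff (positive edge) or r <= -cutoff (negative edge).

    Zero-variance profiles have undefined correlation and are excluded
    from pairing, with a log entry.
    """
    values = _transform(matrix.values, transform)
    sds = values.std(axis=1)
    usable = sds > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("correlation_edges: excluded %d zero-variance profiles", n_dropped)
    ids = [p for p, u in zip(matrix.protein_ids, usable) if u]
    sub = values[usable]
    if len(ids) < 2:
        return []
    corr = np.corrcoef(sub)
    edges: list[Edge] = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(corr[i, j])
            if r >= cutoff:
                edges.append(Edge(ids[i], ids[j], r, "+"))
            elif r <= -cutoff:
                edges.append(Edge(ids[i], ids[j], r, "-"))
    return edges


def hierarchical_modules(
    matrix: AbundanceMatrix,
    k: int = 12,
    method: str = "average",
) -> dict[str, int]:
    """Agglomerative modules on correlation distance of z-scored profiles.

    Distance = 1 - Pearson r; the tree is cut to exactly ``k`` clusters.
    Module ids 1..k are ordered by decreasing size, ties broken by the
    lexicographically first member.
    """
    n = len(matrix.protein_ids)
    if k > n:
        raise ValueError(f"cannot cut {n} proteins into {k} modules")
    values = _transform(matrix.values, "zscore")
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    clusters: dict[int, list[str]] = {}
    for pid, c in zip(matrix.protein_ids, raw):
        clusters.setdefault(int(c), []).append(pid)
    ordered = sorted(clusters.values(), key=lambda members: (-len(members), sorted(members)[0]))
    assignment: dict[str, int] = {}
    for module_id, members in enumerate(ordered, start=1):
        for pid in members:
            assignment[pid] = module_id
    return assignment


def build_network(
    matrix: AbundanceMatrix,
    selected: set[str],
    config: Config | None = None,
) -> CoabundanceNetwork:
    config = config or Config()
    ids = [p for p in matrix.protein_ids if p in selected]
    if not ids:
        return CoabundanceNetwork(nodes=[], edges=[])
    sub = matrix.restrict(ids)
    edges = correlation_edges(sub, config.correlation_cutoff, config.correlation_transform)
    k = min(config.n_modules, len(ids))
    modules = hierarchical_modules(sub, k=k, method=config.linkage_method)
    logger.info(
        "network: %d nodes, %d edges (|r|>=%.2f), %d modules",
        len(ids), len(edges), config.correlation_cutoff, k,
    )
    return CoabundanceNetwork(nodes=ids, edges=edges, modules=modules)


def network_measures(network: CoabundanceNetwork) -> tuple[pd.DataFrame, dict]:
    """Per-node degree and clustering coefficient plus global summaries.

    Edge sign is ignored for topology.
    """
    g = network.graph()
    degree = dict(g.degree())
    clustering = nx.clustering(g)
    node_table = pd.DataFrame(
        {
            "protein_id": network.nodes,
            "module": [network.modules.get(p, 0) for p in network.nodes],
            "degree": [degree[p] for p in network.nodes],
            "clustering_coefficient": [clustering[p] for p in network.nodes],
        }
    )
    global_measures = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_components": nx.number_connected_components(g) if g.number_of_nodes() else 0,
        "density": nx.density(g) if g.number_of_nodes() > 1 else 0.0,
    }
    return node_table, global_measures


def edge_frame(network: CoabundanceNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [e.source for e in network.edges],
            "target": [e.target for e in network.edges],
            "r": [e.r for e in network.edges],
            "sign": [e.sign for e in network.edges],
        }
    )


def write_graphml(network: CoabundanceNetwork, path) -> None:
    """Graph exchange for external viewers (GraphML via networkx)."""
    g = network.graph()
    nx.set_node_attributes(g, {p: m for p, m in network.modules.items()}, "module")
    nx.write_graphml(g, path)
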
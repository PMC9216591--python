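"""Maximum-information shortest paths between genes and between clusters.

When gene i is perturbed, row i of the PRS matrix gives the response of every
other gene.  Taking those responses as node weights, the *PRS path* from i to
j is the unweighted shortest path that maximizes the summed response of its
nodes — among all shortest paths, the corridor carrying the most perturbation
signal.  Between an effector cluster and a sensor cluster, the PRS path is
the highest-weight path over all member pairs.

Selection runs as a dynamic program on the BFS shortest-path DAG, so the
maximum is exact even when the number of distinct shortest paths is
astronomically large.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .node_classes import NodeCluster
from .prs import PRSResult


@dataclass
class PRSPath:
    source: object
    target: object
    nodes: list
    node_weights: list[float]
    total_weight: float

    def __len__(self) -> int:
        return len(self.nodes)


def _bfs_dag(net: nx.Graph, source) -> tuple[dict, dict]:
    """BFS levels and shortest-path predecessor lists from source."""
    dist = {source: 0}
    preds: dict = {source: []}
    frontier = [source]
    d = 0
    while frontier:
        nxt = []
        for u in frontier:
            for v in net.neighbors(u):
                if v not in dist:
                    dist[v] = d + 1
                    preds[v] = [u]
                    nxt.append(v)
                elif dist[v] == d + 1:
                    preds[v].append(u)
        frontier = nxt
        d += 1
    return dist, preds

def prs_path(prs: PRSResult, net: nx.Graph, source, target) -> PRSPath:
    """Highest-weight shortest path from source to target.

    Node weights are row ``source`` of the PRS matrix (the response of every
    gene to perturbation at the source), summed over all path nodes including
    both endpoints.  Ties on total weight are broken by the lexicographically
    smallest node sequence, so the result is deterministic.
    """
    if source == target:
        raise ValueError("source and target must differ")
    for v in (source, target):
        if v not in net:
            raise ValueError(f"node {v!r} not in network")
    dist, preds = _bfs_dag(net, source)
    if target not in dist:
        raise ValueError(f"{target!r} unreachable from {source!r}")
    widx = {v: i for i, v in enumerate(prs.nodes)}
    row = prs.matrix[widx[source]]
    weight = {v: float(row[widx[v]]) for v in dist}

    # restrict the BFS DAG to nodes on some shortest source->target path
    on_path = {target}
    frontier = [target]
    while frontier:
        nxt = []
        for v in frontier:
            for p in preds[v]:
                if p not in on_path:
                    on_path.add(p)
                    nxt.append(p)
        frontier = nxt
    succs: dict = {v: [] for v in on_path}
    for v in on_path:
        for p in preds[v]:
            succs[p].append(v)

    # suffix DP: g[v] = max total weight of v..target within the DAG
    g = {target: weight[target]}
    for v in sorted(on_path - {target}, key=lambda v: -dist[v]):
        g[v] = weight[v] + max(g[u] for u in succs[v])

    # forward walk choosing, among argmax successors, the smallest label:
    # yields the lexicographically smallest maximum-weight node sequence
    nodes = [source]
    v = source
    while v != target:
        m = max(g[u] for u in succs[v])
        v = min((u for u in succs[v] if g[u] == m), key=str)
        nodes.append(v)
    weights = [weight[v] for v in nodes]
    return PRSPath(
        source=source,
        target=target,
        nodes=nodes,
        node_weights=weights,
        total_weight=float(sum(weights)),
    )


def cluster_pair_path(
    prs: PRSResult,
    net: nx.Graph,
    effector_cluster: NodeCluster,
    sensor_cluster: NodeCluster,
    normalize_length: bool = False,
) -> PRSPath:
    """Highest-weight PRS path over all (effector, sensor) member pairs.

    Ties on total weight are broken by shorter path, then by lexicographic
    node sequence.  With ``normalize_length`` the per-node mean weight is
    maximized instead of the raw total.
    """
    e_members = set(effector_cluster.members)
    s_members = set(sensor_cluster.members)
    if e_members & s_members:
        raise ValueError("clusters must be disjoint")
    candidates = []
    for e in sorted(e_members, key=str):
        dist, _ = _bfs_dag(net, e)
        for s in sorted(s_members, key=str):
            if s in dist:
                candidates.append(prs_path(prs, net, e, s))
    if not candidates:
        raise ValueError("no connected effector-sensor pair")

    def score(p: PRSPath):
        w = p.total_weight / len(p) if normalize_length else p.total_weight
        return (-w, len(p), [str(v) for v in p.nodes])

    return min(candidates, key=score)


def paths_table(paths: list[PRSPath]):
    """TSV-ready table of selected paths."""
    import pandas as pd

    return pd.DataFrame(
        {
            "source": [p.source for p in paths],
            "target": [p.target for p in paths],
            "length": [len(p) for p in paths],
            "total_weight": [p.total_weight for p in paths],
            "nodes": ["|".join(map(str, p.nodes)) for p in paths],
        }
    )
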
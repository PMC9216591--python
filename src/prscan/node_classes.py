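"""Sensor/effector selection, clusters, antenna motifs, and edge enrichment.

Sensors are the nodes in the top percentile of sensitivity; effectors the top
percentile of effectiveness.  Connected components of the induced
member-only subgraph with at least ``min_size`` nodes form sensor (effector)
clusters.  A cluster whose members touch exactly one non-member node is an
*antenna motif*: an information bottleneck where perturbation effects enter
the cluster but cannot easily escape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class NodeClassSet:
    """Top-fraction node selection for one role (sensor or effector)."""

    role: str
    fraction: float
    members: list


@dataclass
class NodeCluster:
    """Connected component of the member-only subgraph."""

    id: str
    members: list
    connectors: list = field(default_factory=list)
    is_antenna: bool = False


@dataclass
class EdgeEnrichment:
    """Within-class edge percentage vs degree-matched random node sets."""

    observed_pct: float
    null_pcts: np.ndarray
    fold: float
    p: float
    n_samples: int
    seed: int


def round_half_up(x: float) -> int:
    """Round half away from zero (5183*0.01 -> 52, 1145*0.05 -> 57)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def select_top(values: pd.Series, fraction: float, role: str = "sensor") -> NodeClassSet:
    """Select the round(fraction * n) nodes with the largest profile values.

    Ties at the k-th value are broken by descending value then ascending node
    label, so the selection is deterministic.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(values)
    k = round_half_up(fraction * n)
    if k < 1:
        raise ValueError(f"fraction {fraction} of {n} nodes selects no node")
    order = sorted(values.items(), key=lambda kv: (-kv[1], str(kv[0])))
    members = [node for node, _ in order[:k]]
    return NodeClassSet(role=role, fraction=fraction, members=members)


def find_clusters(
    cls: NodeClassSet, net: nx.Graph, min_size: int = 3
) -> tuple[list[NodeCluster], list]:
    """Connected components of the member-induced subgraph.

    Returns (clusters, unclustered): components with >= min_size members,
    labeled by descending size then lexicographic smallest member, and the
    members left outside any cluster.
    """
    missing = [m for m in cls.members if m not in net]
    if missing:
        raise ValueError(f"class members absent from network: {missing[:5]}")
    sub = net.subgraph(cls.members)
    comps = sorted(
        nx.connected_components(sub), key=lambda c: (-len(c), min(map(str, c)))
    )
    clusters, unclustered = [], []
    idx = 0
    for comp in comps:
        if len(comp) >= min_size:
            idx += 1
            clusters.append(
                NodeCluster(
                    id=f"{cls.role[0].upper()}C{idx}",
                    members=sorted(comp, key=str),
                )
            )
        else:
            unclustered.extend(sorted(comp, key=str))
    return clusters, unclustered


def detect_antenna(
    cluster: NodeCluster, cls: NodeClassSet, net: nx.Graph
) -> NodeCluster:
    """Flag a cluster as an antenna motif and record its connectors.

    Connectors are the non-member nodes adjacent to any cluster member; a
    cluster with exactly one connector is antenna-shaped.
    """
    member_set = set(cls.members)
    connectors = sorted(
        {
            nbr
            for m in cluster.members
            for nbr in net.neighbors(m)
            if nbr not in member_set
        },
        key=str,
    )
    if not connectors and set(net.nodes()) == set(cluster.members):
        raise ValueError("cluster spans the whole network; no exterior exists")
    cluster.connectors = connectors
    cluster.is_antenna = len(connectors) == 1
    return cluster


def neighbor_degree_stats(cls: NodeClassSet, net: nx.Graph) -> dict:
    """Compare average neighbor degree of class members vs the other nodes.

    Uses the unpaired Mann-Whitney/rank-sum test (two-group, no natural
    pairing exists between a class of k nodes and the n-k others).
    Isolated nodes have no neighbor degree and are excluded with a notice.
    """
    avg_nbr = nx.average_neighbor_degree(net)
    isolated = [v for v in net if net.degree(v) == 0]
    if isolated:
        logger.info("excluding %d isolated nodes", len(isolated))
    member_set = set(cls.members)
    in_vals = [avg_nbr[v] for v in net if v in member_set and net.degree(v) > 0]
    out_vals = [avg_nbr[v] for v in net if v not in member_set and net.degree(v) > 0]
    if not in_vals or not out_vals:
        raise ValueError("one comparison group is empty")
    stat, p = stats.mannwhitneyu(in_vals, out_vals, alternative="less")
    return {
        "class_mean": float(np.mean(in_vals)),
        "rest_mean": float(np.mean(out_vals)),
        "statistic": float(stat),
        "p": float(p),
        "n_class": len(in_vals),
        "n_rest": len(out_vals),
    }


def _within_pct(members: set, net: nx.Graph) -> float:
    """Percent of the group's edge endpoints that are group-internal."""
    within = 0
    total = 0
    for m in members:
        for nbr in net.neighbors(m):
            total += 1
            if nbr in members:
                within += 1
    if total == 0:
        return 0.0
    return 100.0 * within / total


def edge_enrichment(
    cls: NodeClassSet,
    net: nx.Graph,
    n_samples: int = 1000,
    rng_seed: int = 0,
) -> EdgeEnrichment:
    """Within-class edge enrichment against degree-matched random node sets.

    Each null sample draws, for every class member, a distinct random node of
    identical degree (falling back to the nearest available degree when the
    exact degree class is exhausted, with a logged notice); the same
    within-group edge percentage is computed for the sample.  The permutation
    p-value is (r+1)/(n+1) with r the number of null percentages at least as
    large as the observed one; fold = observed / mean(null).
    """
    rng = np.random.default_rng(rng_seed)
    member_set = set(cls.members)
    degrees = dict(net.degree())
    by_degree: dict[int, list] = {}
    for v, d in degrees.items():
        by_degree.setdefault(d, []).append(v)
    for d in by_degree:
        by_degree[d].sort(key=str)
    avail_degrees = np.array(sorted(by_degree))

    observed = _within_pct(member_set, net)
    member_degs = sorted(degrees[m] for m in cls.members)

    fallback_logged = False
    null_pcts = np.empty(n_samples)
    for s in range(n_samples):
        chosen: set = set()
        for d in member_degs:
            pool = [v for v in by_degree[d] if v not in chosen]
            if not pool:
                # nearest-degree fallback
                if not fallback_logged:
                    logger.info("exact degree class exhausted; nearest-degree fallback")
                    fallback_logged = True
                for dd in avail_degrees[np.argsort(np.abs(avail_degrees - d))]:
                    pool = [v for v in by_degree[dd] if v not in chosen]
                    if pool:
                        break
                else:
                    raise ValueError("degree-matched sampling impossible")
            chosen.add(pool[rng.integers(len(pool))])
        null_pcts[s] = _within_pct(chosen, net)

    r = int(np.sum(null_pcts >= observed))
    p = (r + 1) / (n_samples + 1)
    null_mean = float(null_pcts.mean())
    fold = observed / null_mean if null_mean > 0 else math.inf
    return EdgeEnrichment(
        observed_pct=observed,
        null_pcts=null_pcts,
        fold=fold,
        p=p,
        n_samples=n_samples,
        seed=rng_seed,
    )


def class_table(
    cls: NodeClassSet, clusters: list[NodeCluster], unclustered: list
) -> pd.DataFrame:
    """TSV-ready table: node, role, cluster id, antenna flag, connectors."""
    rows = []
    for c in clusters:
        for m in c.members:
            rows.append(
                {
                    "node": m,
                    "role": cls.role,
                    "cluster": c.id,
                    "antenna": c.is_antenna,
                    "connectors": ";".join(map(str, c.connectors)),
                }
            )
    for m in unclustered:
        rows.append(
            {"node": m, "role": cls.role, "cluster": "", "antenna": False,
             "connectors": ""}
        )
    return pd.DataFrame(rows)
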
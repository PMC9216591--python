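"""Degree-preserving rewiring nulls, permutation tests, empirical p-values.

The null model for "is this network property more than a consequence of the
degree sequence?" is an ensemble of rewired replicates produced by connected
double-edge swaps: each swap exchanges the endpoints of two random edges and
is accepted only if it creates no duplicate edge or self-loop and does not
disconnect the network, so every replicate keeps the exact degree of every
node.  Empirical p-values follow p = (r+1)/(n+1), with ties counted as
exceedances (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import gnm, node_classes, prs

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed: float
    r: int
    n: int
    p: float
    direction: str
    seed: int | None = None


@dataclass
class RewiredEnsemble:
    """Per-replicate summary statistics of a degree-preserving null ensemble."""

    summaries: pd.DataFrame  # one row per replicate
    seeds: list[int]
    master_seed: int


def rewire(
    net: nx.Graph, swap_multiplier: int = 10, rng_seed: int = 0
) -> nx.Graph:
    """Degree-preserving connected rewiring by double-edge swaps.

    Performs ``swap_multiplier * |E|`` accepted swaps (default 10x the edge
    count) while keeping the network connected; the degree of every node is
    preserved exactly.  Networks too small to admit any valid swap (e.g. a
    triangle) are returned unchanged with a warning.
    """
    if not nx.is_connected(net):
        raise ValueError("rewiring requires a connected network")
    m = net.number_of_edges()
    if m < 2:
        raise ValueError("rewiring requires at least 2 edges")
    g = net.copy()
    nswap = swap_multiplier * m
    if net.number_of_nodes() < 4:
        logger.warning("network too small for any valid swap; returning copy")
        return g
    try:
        nx.connected_double_edge_swap(g, nswap=nswap, seed=rng_seed)
    except nx.NetworkXError as exc:
        logger.warning("rewiring aborted (%s); returning copy", exc)
        return net.copy()
    return g


def empirical_pvalue(
    observed: float, null_values, direction: str = "greater"
) -> PermutationResult:
    """Empirical p = (r+1)/(n+1) against a sample of null statistics.

    ``r`` counts null values at least as extreme as the observed one in the
    stated direction; ties count as extreme.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null_values is empty")
    if direction == "greater":
        r = int(np.sum(null_values >= observed))
    elif direction == "less":
        r = int(np.sum(null_values <= observed))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = null_values.size
    return PermutationResult(
        observed=float(observed), r=r, n=n, p=(r + 1) / (n + 1), direction=direction
    )


def permutation_test(
    values: pd.Series,
    group,
    n_shuffles: int = 10_000,
    rng_seed: int = 0,
    direction: str = "greater",
) -> PermutationResult:
    """Label-shuffling test on mean(group) - mean(rest).

    The per-node values are shuffled ``n_shuffles`` times; each shuffle
    recomputes the difference in means between the (fixed-size) group and
    the rest, and the empirical p-value formula is applied.
    """
    group = set(group)
    if not group:
        raise ValueError("group is empty")
    if len(group) >= len(values):
        raise ValueError("group must be a proper subset of the nodes")
    vals = values.to_numpy(dtype=float)
    mask = np.array([node in group for node in values.index])
    k = int(mask.sum())
    observed = vals[mask].mean() - vals[~mask].mean()

    rng = np.random.default_rng(rng_seed)
    n = vals.size
    # difference of means is a linear function of the group sum
    total = vals.sum()
    def diff_from_group_sum(gs: np.ndarray) -> np.ndarray:
        return gs / k - (total - gs) / (n - k)

    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        idx = rng.choice(n, size=k, replace=False)
        null[s] = vals[idx].sum()
    null = diff_from_group_sum(null)
    res = empirical_pvalue(observed, null, direction=direction)
    res.seed = rng_seed
    return res


def _replicate_summary(
    g: nx.Graph, fraction: float, min_size: int, convention: str
) -> dict:
    """GNM + PRS + sensor/effector selection summary for one network."""
    model = gnm.build_laplacian(g)
    cov = gnm.compute_covariance(model)
    res = prs.compute_prs(cov, convention=convention)
    eff = res.effectiveness
    sen = res.sensitivity
    deg = pd.Series(dict(g.degree()), dtype=float).reindex(eff.index)
    sensors = node_classes.select_top(sen, fraction, role="sensor")
    effectors = node_classes.select_top(eff, fraction, role="effector")
    s_clusters, _ = node_classes.find_clusters(sensors, g, min_size=min_size)
    e_clusters, _ = node_classes.find_clusters(effectors, g, min_size=min_size)
    return {
        "mean_effectiveness": float(eff.mean()),
        "mean_sensitivity": float(sen.mean()),
        "degree_effectiveness_r": float(stats.pearsonr(deg, eff)[0]),
        "degree_sensitivity_rho": float(stats.spearmanr(deg, sen)[0]),
        "n_sensor_clusters": len(s_clusters),
        "n_effector_clusters": len(e_clusters),
    }


def ensemble_stats(
    net: nx.Graph,
    n_replicates: int = 100,
    swap_multiplier: int = 10,
    fraction: float = 0.01,
    min_size: int = 3,
    convention: str = "squared",
    rng_seed: int = 0,
) -> RewiredEnsemble:
    """Rewire, re-run the GNM/PRS pipeline, and summarize each replicate.

    A master seed deterministically spawns one seed per replicate, so the
    ensemble is reproducible bit-for-bit given the same seed.
    """
    master = np.random.default_rng(rng_seed)
    seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_replicates)]
    rows = []
    for seed in seeds:
        g = rewire(net, swap_multiplier=swap_multiplier, rng_seed=seed)
        row = _replicate_summary(g, fraction, min_size, convention)
        row["seed"] = seed
        rows.append(row)
    return RewiredEnsemble(
        summaries=pd.DataFrame(rows), seeds=seeds, master_seed=rng_seed
    )


def observed_summary(
    net: nx.Graph,
    fraction: float = 0.01,
    min_size: int = 3,
    convention: str = "squared",
) -> dict:
    """The same per-network summary computed for the real (unrewired) network."""
    return _replicate_summary(net, fraction, min_size, convention)
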
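"""Synthetic networks and annotations with known ground truth.

The planted core-periphery generator emulates the topology in which sensor
genes live in real profile-similarity networks: a dense random core (the
bulk of the network, containing the high-degree effector-like hubs) plus
small low-degree "antenna" clusters, each a connected clique hanging off the
core through a single connector node.  Perturbation-response scanning on such
a network should rank antenna members high in sensitivity and core hubs high
in effectiveness, and degree-preserving rewiring should destroy the planted
clusters — so every downstream module is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import networkx as nx
import numpy as np

from .go_enrichment import AnnotationSet


@dataclass
class PlantedNetwork:
    network: nx.Graph
    core_nodes: list
    antenna_clusters: list  # list of (member list, connector) tuples
    labels: dict  # node -> "core" | "antenna"
    params: dict


def make_core_periphery(
    n_core: int = 30,
    p_core: float = 0.4,
    n_antennas: int = 3,
    antenna_size: int = 4,
    rng_seed: int = 0,
    max_retries: int = 20,
) -> PlantedNetwork:
    """Dense Erdos-Renyi core with clique antennas on single connectors.

    Each antenna is a clique of ``antenna_size`` nodes joined to the core by
    one edge from its first member to a core node of median degree (so the
    sensitivity signal of antenna nodes is attributable to the motif
    topology, not to an unusual connector degree).  Regenerates the core with
    a fresh seed until it is connected, up to ``max_retries``.
    """
    if antenna_size < 3:
        raise ValueError("antenna clusters require >= 3 nodes")
    if n_core < 3 or n_antennas < 1:
        raise ValueError("parameters must be positive (core >= 3 nodes)")
    rng = np.random.default_rng(rng_seed)
    core = None
    for _ in range(max_retries):
        seed = int(rng.integers(0, 2**31 - 1))
        g = nx.gnp_random_graph(n_core, p_core, seed=seed)
        if nx.is_connected(g):
            core = g
            break
    if core is None:
        raise RuntimeError(f"core not connected after {max_retries} retries")
    net = nx.relabel_nodes(core, {i: f"core{i:03d}" for i in core.nodes()})
    core_nodes = sorted(net.nodes())

    # connectors: core nodes of median degree, distinct per antenna
    by_median = sorted(
        core_nodes, key=lambda v: (abs(net.degree(v) - _median_degree(net)), v)
    )
    if n_antennas > len(by_median):
        raise ValueError("more antennas than available connector nodes")
    antenna_clusters = []
    labels = {v: "core" for v in core_nodes}
    for a in range(n_antennas):
        members = [f"ant{a}_{k:02d}" for k in range(antenna_size)]
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                net.add_edge(u, v)
        connector = by_median[a]
        net.add_edge(members[0], connector)
        antenna_clusters.append((members, connector))
        for m in members:
            labels[m] = "antenna"
    assert nx.is_connected(net)
    return PlantedNetwork(
        network=net,
        core_nodes=core_nodes,
        antenna_clusters=antenna_clusters,
        labels=labels,
        params={
            "n_core": n_core,
            "p_core": p_core,
            "n_antennas": n_antennas,
            "antenna_size": antenna_size,
            "rng_seed": rng_seed,
        },
    )


def _median_degree(net: nx.Graph) -> float:
    return float(np.median([d for _, d in net.degree()]))


def make_closed_form_graphs() -> dict:
    """Catalogue of small graphs with analytic covariance/PRS expectations.

    Values are exact rationals derived by hand from the Laplacian
    pseudo-inverse: the 3-node path from its two nonzero eigenpairs, K_n from
    Gamma^+ = (1/n)(I - J/n).
    """
    path3 = nx.path_graph([1, 2, 3])
    k5 = nx.complete_graph(5)
    star10 = nx.star_graph(9)  # hub 0 + 9 leaves
    cycle6 = nx.cycle_graph(6)
    barbell = nx.barbell_graph(5, 2)
    return {
        "path3": {
            "graph": path3,
            # C for gamma=1: eigenpairs (1, (1,0,-1)/sqrt2), (3, (1,-2,1)/sqrt6)
            "cov": {
                (1, 1): Fraction(5, 9),
                (2, 2): Fraction(2, 9),
                (1, 2): Fraction(-1, 9),
                (1, 3): Fraction(-4, 9),
            },
            "resistance_1_3": Fraction(2),  # two unit springs in series
            # squared PRS: P_ij = C_ij^2 / C_ii^2
            "prs": np.array(
                [
                    [1.0, 1 / 25, 16 / 25],
                    [1 / 4, 1.0, 1 / 4],
                    [16 / 25, 1 / 25, 1.0],
                ]
            ),
            "effectiveness": np.array([42 / 75, 3 / 6, 42 / 75]) / 1,
        },
        "k5": {
            "graph": k5,
            "cov_diag": Fraction(4, 25),
            "cov_offdiag": Fraction(-1, 25),
            # rows: {1, four entries of (1/25)^2/(4/25)^2 = 1/16}
            "effectiveness_const": Fraction(1, 4),  # (1 + 4/16)/5
        },
        "star10": {"graph": star10, "leaves": list(range(1, 10))},
        "cycle6": {"graph": cycle6},
        "barbell": {"graph": barbell},
    }


def make_annotations(
    planted: PlantedNetwork,
    n_terms: int = 20,
    background_rate: float = 0.1,
    rng_seed: int = 0,
) -> tuple[AnnotationSet, dict]:
    """Annotation fixture: one enriched term per antenna plus background noise.

    Each antenna cluster gets a dedicated "signal" term annotating all of its
    members; the remaining terms annotate uniformly random genes at
    ``background_rate``.  Returns the AnnotationSet and the ground truth
    mapping cluster index -> signal term id.
    """
    rng = np.random.default_rng(rng_seed)
    population = sorted(planted.network.nodes())
    n_signal = len(planted.antenna_clusters)
    if n_terms <= n_signal:
        raise ValueError("need more terms than antenna clusters")
    gene_terms: dict = {}
    truth = {}
    for a, (members, _) in enumerate(planted.antenna_clusters):
        term = f"GO:SIG{a:04d}"
        truth[a] = term
        for m in members:
            gene_terms.setdefault(m, set()).add(term)
    for b in range(n_terms - n_signal):
        term = f"GO:BG{b:05d}"
        hits = rng.random(len(population)) < background_rate
        for g, hit in zip(population, hits):
            if hit:
                gene_terms.setdefault(g, set()).add(term)
    ann = AnnotationSet(
        ontology=None,
        gene_terms=gene_terms,
        population=set(population),
        term_names={},
    )
    return ann, truth


def write_gaf(ann: AnnotationSet, path: str | Path, evidence: str = "IDA") -> None:
    """Write an AnnotationSet as a minimal GAF 2.2 file (symbol = gene id)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(ann.gene_terms, key=str):
            for term in sorted(ann.gene_terms[gene]):
                fh.write(
                    f"DB\t{gene}\t{gene}\t\t{term}\tREF\t{evidence}"
                    f"\t\tP\t\t\tgene\ttaxon:0\t20220310\tDB\t\t\n"
                )


def write_obo(terms: list[str], path: str | Path) -> None:
    """Write a flat toy OBO 1.2 ontology containing the given terms."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for t in sorted(terms):
            fh.write(f"[Term]\nid: {t}\nname: name of {t}\nnamespace: biological_process\n\n")
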
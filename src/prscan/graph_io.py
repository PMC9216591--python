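"""Read similarity matrices and edge lists; build thresholded undirected networks.

The primary input emulates a genetic-interaction profile-similarity matrix:
a square, symmetric, tab-delimited table of Pearson correlations between the
genome-wide interaction profiles of gene pairs.  Thresholding the matrix at a
correlation cutoff yields an unweighted, undirected profile-similarity network
whose giant component feeds the elastic-network analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: absolute tolerance beyond which an asymmetric similarity matrix is rejected
ASYMMETRY_TOL = 1e-8


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of profile-similarity scores (PCC, in [-1, 1])."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{n} gene identifiers"
            )
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene identifiers")
        asym = np.abs(self.scores - self.scores.T).max() if n else 0.0
        if asym > ASYMMETRY_TOL:
            raise ValueError(
                f"similarity matrix asymmetric beyond tolerance "
                f"(max |S - S^T| = {asym:.3g} > {ASYMMETRY_TOL:g})"
            )

    @property
    def n(self) -> int:
        return len(self.gene_ids)


def read_similarity_matrix(path: str | Path, dialect: str = "tsv") -> SimilarityMatrix:
    """Parse a gene-by-gene similarity table with header row and column.

    Parameters
    ----------
    path
        Tab-delimited file: first row and first column carry gene identifiers.
    dialect
        ``"tsv"`` (tab) or ``"csv"`` (comma).

    Raises
    ------
    ValueError
        On ragged/non-numeric tables, duplicate gene ids, or asymmetry
        beyond ``ASYMMETRY_TOL`` (silent symmetrization would hide data
        integrity problems).
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    gene_ids = [str(g) for g in df.index]
    col_ids = [str(g) for g in df.columns]
    if gene_ids != col_ids:
        raise ValueError("row and column gene identifiers differ")
    try:
        scores = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in similarity matrix: {exc}") from exc
    return SimilarityMatrix(gene_ids=gene_ids, scores=scores)


def threshold_network(
    sim: SimilarityMatrix, cutoff: float, strict: bool = True
) -> nx.Graph:
    """Build the unweighted similarity network at a correlation cutoff.

    An edge (i, j) is present iff score(i, j) > cutoff (``strict``) or
    >= cutoff.  Genes with no passing edge are dropped; the diagonal never
    yields edges.  The strict default reproduces the published yeast network
    node/edge counts at cutoff 0.2.
    """
    if not -1 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (-1, 1], got {cutoff}")
    s = sim.scores
    mask = (s > cutoff) if strict else (s >= cutoff)
    np.fill_diagonal(mask, False)
    g = nx.Graph()
    ii, jj = np.nonzero(np.triu(mask, k=1))
    ids = sim.gene_ids
    g.add_edges_from((ids[i], ids[j]) for i, j in zip(ii, jj))
    return g


def giant_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph of the largest connected component.

    Ties on size are broken by the smallest lexicographic node label so the
    result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no giant component")
    comps = sorted(
        nx.connected_components(net), key=lambda c: (-len(c), min(c))
    )
    return net.subgraph(comps[0]).copy()


def read_edge_list(path: str | Path, on_self_loop: str = "error") -> nx.Graph:
    """Read a two-column tab-delimited edge list into a simple graph.

    Extra columns (e.g. weights) are ignored with a logged notice.
    Self-loop rows are rejected (``on_self_loop="error"``) or dropped with a
    warning (``"warn"``).
    """
    g = nx.Graph()
    extra_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            if len(parts) > 2 and not extra_seen:
                logger.info("%s: extra columns beyond 2 ignored", path)
                extra_seen = True
            u, v = parts[0], parts[1]
            if u == v:
                if on_self_loop == "warn":
                    logger.warning("%s:%d: self-loop %r dropped", path, lineno, u)
                    continue
                raise ValueError(f"{path}:{lineno}: self-loop on {u!r}")
            g.add_edge(u, v)
    return g


def write_network(net: nx.Graph, path: str | Path, format: str = "tsv") -> None:
    """Write a network as a two-column TSV edge list, GraphML, or SIF."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for u, v in sorted(map(sorted, net.edges())):
                fh.write(f"{u}\t{v}\n")
    elif format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(map(sorted, net.edges())):
                fh.write(f"{u}\tsim\t{v}\n")
            for node in sorted(nx.isolates(net)):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path: str | Path, format: str = "tsv") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    if format == "tsv":
        return read_edge_list(path)
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown format {format!r}")
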
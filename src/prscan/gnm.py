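"""Gaussian network model: Kirchhoff/Laplacian matrix and its pseudo-inverse.

A network is modelled as an elastic bead-and-spring system.  Connectivity is
encoded in the Kirchhoff (graph Laplacian) matrix Gamma: diagonal entries are
node degrees, off-diagonal entries are -1 for connected pairs and 0 otherwise.
The covariance of the equilibrium node fluctuations is C = (1/gamma) Gamma^+,
the scaled Moore-Penrose pseudo-inverse restricted to the nonzero modes; the
diagonal sigma_i = C_ii is the square fluctuation of node i, an intrinsic
property of the topology.  gamma is a uniform spring constant that only
rescales C, so all quantities are in arbitrary units (default gamma = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

#: dense eigendecomposition contract; larger networks are rejected explicitly
MAX_DENSE_N = 10_000

#: relative null-space tolerance (times the largest eigenvalue)
ZERO_MODE_RTOL = 1e-8


@dataclass
class GNMModel:
    """Laplacian and eigendecomposition of a connected network."""

    nodes: list
    laplacian: np.ndarray
    gamma: float
    eigenvalues: np.ndarray   # ascending
    eigenvectors: np.ndarray  # columns orthonormal, aligned with eigenvalues
    zero_mode_tol: float

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class Covariance:
    """C = (1/gamma) Gamma^+ over nonzero modes; sigma is its diagonal."""

    nodes: list
    matrix: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        return np.diag(self.matrix)


def build_laplacian(net: nx.Graph, gamma: float = 1.0) -> GNMModel:
    """Build the Kirchhoff matrix of a connected network and eigendecompose it.

    The node order of the model is the sorted node-label order, so results are
    independent of graph construction order.

    Raises
    ------
    ValueError
        If the network is disconnected (extract the giant component first),
        has fewer than two nodes, or exceeds the dense-eigendecomposition
        size contract.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError(f"GNM requires >= 2 nodes, got {n}")
    if n > MAX_DENSE_N:
        raise ValueError(
            f"network of {n} nodes exceeds the dense eigendecomposition "
            f"contract ({MAX_DENSE_N}); no sparse fallback is provided"
        )
    if not nx.is_connected(net):
        raise ValueError(
            "network is disconnected; extract the giant component first"
        )
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    nodes = sorted(net.nodes())
    lap = nx.laplacian_matrix(net, nodelist=nodes).toarray().astype(float)
    evals, evecs = np.linalg.eigh(lap)
    tol = ZERO_MODE_RTOL * evals[-1]
    if evals[0] < -tol:
        raise ValueError(f"negative Laplacian eigenvalue {evals[0]:.3g}")
    n_zero = int(np.sum(evals < tol))
    if n_zero != 1:
        raise ValueError(
            f"{n_zero} near-zero eigenvalues: network must be connected"
        )
    return GNMModel(
        nodes=nodes,
        laplacian=lap,
        gamma=gamma,
        eigenvalues=evals,
        eigenvectors=evecs,
        zero_mode_tol=tol,
    )


def compute_covariance(model: GNMModel) -> Covariance:
    """Covariance C = (1/gamma) * sum_{lambda_k > tol} u_k u_k^T / lambda_k."""
    keep = model.eigenvalues > model.zero_mode_tol
    evals = model.eigenvalues[keep]
    evecs = model.eigenvectors[:, keep]
    c = (evecs / evals) @ evecs.T / model.gamma
    c = (c + c.T) / 2.0  # symmetrize round-off
    return Covariance(nodes=model.nodes, matrix=c)


def effective_resistance(cov: Covariance, i, j) -> float:
    """Effective (electrical) resistance between nodes i, j from C (gamma=1 units)."""
    nodes = cov.nodes
    a, b = nodes.index(i), nodes.index(j)
    c = cov.matrix
    return float(c[a, a] + c[b, b] - 2.0 * c[a, b])
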